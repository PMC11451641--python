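"""Shared fixtures: tiny hand-built graphs, random DAGs, and trained models.

Training fixtures are session-scoped and lazily built so fast unit tests do
not pay for them; every source of randomness is seeded.
"""

from __future__ import annotations

import pytest

from pathkg import kg_data, model, synthetic, training
from pathkg.kg_data import KnowledgeGraph, RelationVocab, Triplet, TypedEntityVocab


def make_graph(
    edges: list[tuple[int, int, int]],
    num_nodes: int | None = None,
    num_relations: int = 1,
    valid: list[tuple[int, int, int]] | None = None,
    test: list[tuple[int, int, int]] | None = None,
    brg: list[tuple[int, int, int]] | None = None,
) -> KnowledgeGraph:
    """Build a minimal graph from raw integer triplets (no reverse augmentation)."""
    n = num_nodes or (max((max(h, t) for h, _, t in edges), default=-1) + 1)
    for extra in (valid or []) + (test or []) + (brg or []):
        n = max(n, extra[0] + 1, extra[2] + 1)
    vocab = TypedEntityVocab()
    for i in range(n):
        vocab.add(f"n{i}")
    rels = RelationVocab()
    for r in range(num_relations):
        rels.encode(f"r{r}", extend=True)
    rels.augment()
    wrap = lambda lst: [Triplet(*e) for e in (lst or [])]
    return KnowledgeGraph(vocab, rels, wrap(edges), wrap(valid), wrap(test), wrap(brg))


# random DAGs and edge weights are shared with the experiment drivers
from pathkg.experiments import random_dag_graph, random_edge_weights, train_run  # noqa: E402,F401


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The standard synthetic benchmark bundle (seed 1) with its manifest."""
    path = tmp_path_factory.mktemp("bundle") / "kg"
    manifest = synthetic.generate(synthetic.SyntheticKGSpec(seed=1), path)
    return path, manifest


@pytest.fixture(scope="session")
def default_graph(default_bundle):
    path, _ = default_bundle
    return kg_data.load_bundle(path)


@pytest.fixture(scope="session")
def trained_default(default_bundle):
    """One model trained at default conditions on the seed-1 benchmark."""
    path, manifest = default_bundle
    graph = kg_data.load_bundle(path)
    cfg = model.ModelConfig(seed=1)
    result = training.train(graph, cfg, training.TrainConfig(seed=1), training.NegativeSamplingConfig(rng_seed=1))
    return graph, cfg, result, manifest


@pytest.fixture(scope="session")
def planted_rule_runs(tmp_path_factory):
    """Default-condition training runs on bundles/seeds 1..5 (recovery checks)."""
    root = tmp_path_factory.mktemp("runs")
    return [train_run(seed, root) for seed in range(1, 6)]
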