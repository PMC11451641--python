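"""Gradient-based path explanations for individual predictions.

The model's prediction p(v | u, q) is locally approximated by a linear model
over paths, so a path's importance is the partial derivative of the
prediction with respect to that path.  Computing this for every path is
intractable; instead the derivative is approximated per *edge*: the gradient
of the prediction with respect to the edge's message weight (one leaf tensor
shared across all propagation layers), reduced to a scalar by summing its
components (an L2 reduction is available).  A path's importance is then the
sum of its edge importances, and the top-k explanations are the k maximum-
importance-sum head→tail paths of length ≤ T, found by an exact k-best
dynamic program over layers.  Negative importances are kept as-is: the linear
surrogate is signed.

The export follows the visualization convention of drawing the top-10 paths
with edge width proportional to how often an edge occurs among them and the
rank-1 path highlighted.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kg_data import KnowledgeGraph, RelationVocab, Triplet, TypedEntityVocab
from .model import ModelConfig, ModelParams, forward, score_logits

DEFAULT_TOP_K = 10


@dataclass
class EdgeImportance:
    """Scalar importance per propagation edge for one (u, q, v) prediction."""

    importance: dict[Triplet, float]
    prediction: float

    def nonzero(self, tol: float = 0.0) -> dict[Triplet, float]:
        return {e: v for e, v in self.importance.items() if abs(v) > tol}


@dataclass
class PathExplanation:
    """Top-k paths (edge sequences) ranked by summed edge importance."""

    paths: list[tuple[tuple[Triplet, ...], float]]
    edge_frequency: dict[Triplet, int] = field(default_factory=dict)
    reason: str | None = None  # set when no path exists

    @property
    def top_path(self) -> tuple[Triplet, ...] | None:
        return self.paths[0][0] if self.paths else None

    def __post_init__(self):
        scores = [s for _, s in self.paths]
        assert scores == sorted(scores, reverse=True), "paths must be sorted by importance"


def edge_importance(
    graph: KnowledgeGraph,
    source: int,
    query_relation: int,
    tail: int,
    config: ModelConfig,
    params: ModelParams,
    reduction: str = "sum",
) -> EdgeImportance:
    """Differentiate p(tail | source, q) w.r.t. every edge's message weight.

    Edges that lie on no source→tail path within T hops receive exactly zero
    (no gradient flows through them).  Deterministic for fixed parameters.
    """
    if reduction not in ("sum", "l2"):
        raise ValueError("reduction must be 'sum' or 'l2'")
    table, leaf = forward(
        graph, np.array([source]), np.array([query_relation]), config, params, capture_edge_weights=True
    )
    prob = score_logits(table.states, config, params).sigmoid()
    p_tail = prob[np.array([0]), np.array([tail])]
    p_tail.backward()
    grad = leaf.grad if leaf.grad is not None else np.zeros_like(leaf.data)
    per_edge = grad[0]  # (E, d)
    if reduction == "sum":
        values = per_edge.sum(axis=1)
    else:
        values = np.sqrt((per_edge**2).sum(axis=1))
    return EdgeImportance(
        importance={e: float(v) for e, v in zip(graph.propagation_edges, values)},
        prediction=float(p_tail.data[0]),
    )


def top_k_paths(
    importance: EdgeImportance,
    graph: KnowledgeGraph,
    head: int,
    tail: int,
    k: int,
    max_len: int,
) -> PathExplanation:
    """Exact k-best head→tail paths of length ≤ max_len by importance sum.

    Dynamic program over path length keeping, per (node, length), the k best
    prefixes; any global top-k path's prefix is itself a kept prefix, so the
    enumeration is exact (no beam pruning).  Parallel edges with different
    relations count as distinct paths.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out_edges: dict[int, list[Triplet]] = {}
    for e in graph.propagation_edges:
        out_edges.setdefault(e.head, []).append(e)

    # frontier[node] = list of (score, path tuple) of exactly-current-length paths
    frontier: dict[int, list[tuple[float, tuple[Triplet, ...]]]] = {head: [(0.0, ())]}
    collected: list[tuple[float, tuple[Triplet, ...]]] = []
    for _ in range(max_len):
        nxt: dict[int, list[tuple[float, tuple[Triplet, ...]]]] = {}
        for node, prefixes in frontier.items():
            for e in out_edges.get(node, []):
                w = importance.importance.get(e, 0.0)
                for s, p in prefixes:
                    nxt.setdefault(e.tail, []).append((s + w, p + (e,)))
        for node in nxt:
            nxt[node] = heapq.nlargest(k, nxt[node], key=lambda sp: sp[0])
        frontier = nxt
        collected.extend(frontier.get(tail, []))

    best = heapq.nlargest(k, collected, key=lambda sp: sp[0])
    if not best:
        return PathExplanation(paths=[], reason=f"no path of length <= {max_len} from {head} to {tail}")
    freq: dict[Triplet, int] = {}
    for _, p in best:
        for e in p:
            freq[e] = freq.get(e, 0) + 1
    return PathExplanation(paths=[(p, s) for s, p in best], edge_frequency=freq)


def explain(
    graph: KnowledgeGraph,
    source: int,
    query_relation: int,
    tail: int,
    config: ModelConfig,
    params: ModelParams,
    k: int = DEFAULT_TOP_K,
    reduction: str = "sum",
) -> tuple[EdgeImportance, PathExplanation]:
    """End-to-end: edge gradients, then the top-k importance-sum paths."""
    imp = edge_importance(graph, source, query_relation, tail, config, params, reduction=reduction)
    expl = top_k_paths(imp, graph, head=source, tail=tail, k=k, max_len=config.layers)
    return imp, expl


def explanation_manifest(
    expl: PathExplanation,
    vocab: TypedEntityVocab,
    relations: RelationVocab,
) -> dict:
    """Paths as readable (node, relation, node, ...) name sequences with scores."""
    paths = []
    for seq, s in expl.paths:
        readable: list[str] = []
        for i, e in enumerate(seq):
            if i == 0:
                readable.append(vocab.id_to_name[e.head])
            readable.append(relations.id_to_name[e.relation])
            readable.append(vocab.id_to_name[e.tail])
        paths.append({"path": readable, "importance": s})
    return {"paths": paths, "reason": expl.reason}


def export_explanation(
    expl: PathExplanation,
    vocab: TypedEntityVocab,
    relations: RelationVocab,
    path: str | Path,
    fmt: str = "graphml",
) -> None:
    """Write the explanation subgraph with the drawing convention attributes.

    Edge attribute ``width`` is the number of top-k paths the edge occurs in;
    edges of the rank-1 path carry ``highlight=True`` (drawn in red by
    downstream plotting); nodes carry name and type labels.
    """
    if not expl.paths:
        raise ValueError(f"empty explanation, nothing to export ({expl.reason})")
    import networkx as nx

    top = set(expl.top_path or ())
    g = nx.MultiDiGraph()
    for e, count in expl.edge_frequency.items():
        for node in (e.head, e.tail):
            if not g.has_node(vocab.id_to_name[node]):
                g.add_node(vocab.id_to_name[node], type=vocab.id_to_type[node])
        g.add_edge(
            vocab.id_to_name[e.head],
            vocab.id_to_name[e.tail],
            relation=relations.id_to_name[e.relation],
            width=count,
            highlight=e in top,
        )
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "dot":
        _write_dot(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def _write_dot(g, path: str | Path) -> None:
    lines = ["digraph explanation {"]
    for node, attrs in g.nodes(data=True):
        lines.append(f'  "{node}" [type="{attrs.get("type", "")}"];')
    for u, v, attrs in g.edges(data=True):
        color = "red" if attrs.get("highlight") else "black"
        lines.append(
            f'  "{u}" -> "{v}" [label="{attrs.get("relation", "")}", '
            f'penwidth={attrs.get("width", 1)}, color={color}];'
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_manifest(expl: PathExplanation, vocab, relations, path: str | Path) -> None:
    Path(path).write_text(json.dumps(explanation_manifest(expl, vocab, relations), indent=1), encoding="utf-8")
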