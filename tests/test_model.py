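"""Neural message passing: indicator, messages, aggregation, propagation,
scoring, and equivalence with the exact sum-product recursion."""

import numpy as np
import pytest

from conftest import make_graph, random_dag_graph, random_edge_weights
from pathkg import semiring
from pathkg.autodiff import Tensor
from pathkg.model import (
    ModelConfig,
    ModelParams,
    aggregate,
    combine_symmetric_logits,
    forward,
    indicator,
    load_checkpoint,
    message,
    save_checkpoint,
    score,
    score_all_tails,
    score_symmetric,
)


def degenerate_config(T: int) -> ModelConfig:
    return ModelConfig(
        layers=T, hidden_dim=1, message_op="multiplication", aggregation="sum",
        score_net_layers=0, layer_norm=False, use_relu=False, seed=0,
    )


class TestConfig:
    def test_rotation_needs_even_dim(self):
        with pytest.raises(ValueError, match="even"):
            ModelConfig(message_op="rotation", hidden_dim=7)

    def test_enums_validated(self):
        with pytest.raises(ValueError):
            ModelConfig(message_op="projection")
        with pytest.raises(ValueError):
            ModelConfig(aggregation="median")


class TestIndicator:
    def test_places_query_on_source_only(self):
        tab = indicator(1, np.array([1.0, 2.0]), 3)
        np.testing.assert_array_equal(tab.states.data[0], [[0, 0], [1, 2], [0, 0]])
        assert tab.layer == 0

    def test_single_node(self):
        tab = indicator(0, np.array([3.0]), 1)
        np.testing.assert_array_equal(tab.states.data[0], [[3.0]])

    def test_row_sum_equals_query(self):
        rng = np.random.default_rng(0)
        q = rng.normal(size=8)
        tab = indicator(4, q, 11)
        np.testing.assert_allclose(tab.states.data[0].sum(axis=0), q)

    def test_out_of_range_source(self):
        with pytest.raises(IndexError):
            indicator(3, np.array([1.0]), 3)


class TestMessage:
    def test_translation_identity(self):
        out = message(Tensor(np.array([1.0, 2.0])), Tensor(np.array([0.0, 0.0])), "translation")
        np.testing.assert_array_equal(out.data, [1.0, 2.0])

    def test_multiplication(self):
        out = message(Tensor(np.array([2.0, 3.0])), Tensor(np.array([1.0, 0.0])), "multiplication")
        np.testing.assert_array_equal(out.data, [2.0, 0.0])

    def test_rotation_quarter_turn(self):
        # 1 + 0i rotated by pi/2 -> 0 + 1i; phases live in the first half of w
        h = Tensor(np.array([1.0, 0.0]))
        w = Tensor(np.array([np.pi / 2, 0.0]))
        out = message(h, w, "rotation")
        np.testing.assert_allclose(out.data, [0.0, 1.0], atol=1e-12)

    def test_rotation_matches_complex_arithmetic(self):
        rng = np.random.default_rng(2)
        d = 6
        h = rng.normal(size=d)
        w = rng.normal(size=d)
        z = (h[:3] + 1j * h[3:]) * np.exp(1j * w[:3])
        out = message(Tensor(h), Tensor(w), "rotation")
        np.testing.assert_allclose(out.data, np.concatenate([z.real, z.imag]), atol=1e-12)

    def test_rotation_preserves_modulus(self):
        rng = np.random.default_rng(3)
        h, w = rng.normal(size=4), rng.normal(size=4)
        out = message(Tensor(h), Tensor(w), "rotation").data
        before = np.abs(h[:2] + 1j * h[2:])
        after = np.abs(out[:2] + 1j * out[2:])
        np.testing.assert_allclose(after, before, atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            message(Tensor(np.ones(3)), Tensor(np.ones(4)), "translation")


class TestAggregate:
    def test_sum_and_max_fixtures(self):
        msgs = [np.array([1.0, 1.0]), np.array([2.0, 0.0])]
        np.testing.assert_array_equal(aggregate(msgs, np.zeros(2), "sum"), [3.0, 1.0])
        msgs = [np.array([1.0, 5.0]), np.array([3.0, 2.0])]
        np.testing.assert_array_equal(aggregate(msgs, np.zeros(2), "max"), [3.0, 5.0])

    def test_empty_messages_reduce_to_boundary(self):
        b = np.array([0.5, -1.0])
        np.testing.assert_array_equal(aggregate([], b, "mean"), b)
        assert np.all(np.isfinite(aggregate([], b, "mean")))

    @pytest.mark.parametrize("mode", ["sum", "mean", "max", "pna"])
    def test_permutation_invariance(self, mode):
        rng = np.random.default_rng(17)
        msgs = [rng.normal(size=6) for _ in range(5)]
        b = rng.normal(size=6)
        kw = {}
        if mode == "pna":
            kw = {"degree_stats": 1.3, "pna_proj": (rng.normal(size=(72, 6)), rng.normal(size=6))}
        base = aggregate(msgs, b, mode, **kw)
        for _ in range(5):
            perm = [msgs[i] for i in rng.permutation(5)]
            np.testing.assert_allclose(aggregate(perm, b, mode, **kw), base, atol=1e-12)


class TestForward:
    def test_zero_layers_is_indicator(self):
        g = make_graph([(0, 0, 1), (1, 0, 2)])
        cfg = ModelConfig(layers=0, hidden_dim=4, seed=1)
        params = ModelParams.initialize(cfg, g.num_relations)
        tab, _ = forward(g, [0], [0], cfg, params)
        expect = np.zeros((3, 4))
        expect[0] = params["query_emb"].data[0]
        np.testing.assert_allclose(tab.states.data[0], expect)

    def test_isolated_node_keeps_boundary_under_sum(self):
        g = make_graph([(0, 0, 1)], num_nodes=3)  # node 2 has no incoming edge
        cfg = ModelConfig(layers=3, hidden_dim=4, aggregation="sum", layer_norm=False, use_relu=False, seed=2)
        params = ModelParams.initialize(cfg, g.num_relations)
        tab, _ = forward(g, [0], [0], cfg, params)
        np.testing.assert_allclose(tab.states.data[0, 2], np.zeros(4), atol=1e-12)

    @pytest.mark.parametrize("trial", range(8))
    def test_degenerate_config_matches_sum_product_recursion(self, trial):
        rng = np.random.default_rng(200 + trial)
        g = random_dag_graph(rng)
        w = random_edge_weights(g, rng)
        T = min(g.num_nodes - 1, 5)
        cfg = degenerate_config(T)
        params = ModelParams.initialize(cfg, g.num_relations)
        params["query_emb"].data[:] = 1.0
        ew = np.array([[w[e]] for e in g.propagation_edges])
        tab, _ = forward(g, [0], [0], cfg, params, edge_weights=ew)
        exact = semiring.generalized_bellman_ford(g, 0, w, semiring.SUM_PRODUCT, T)
        for v in range(g.num_nodes):
            assert abs(tab.states.data[0, v, 0] - exact[v]) < 1e-6

    @pytest.mark.parametrize("op,agg", [("translation", "mean"), ("rotation", "max"), ("multiplication", "pna")])
    def test_variants_run_and_stay_finite(self, op, agg):
        g = make_graph([(0, 0, 1), (1, 0, 2), (2, 1, 0), (0, 1, 2)], num_relations=2)
        cfg = ModelConfig(layers=2, hidden_dim=4, message_op=op, aggregation=agg, seed=5)
        params = ModelParams.initialize(cfg, g.num_relations)
        tab, _ = forward(g, [0, 1], [0, 2], cfg, params)
        assert tab.states.data.shape == (2, 3, 4)
        assert np.all(np.isfinite(tab.states.data))


class TestScoring:
    def test_sigmoid_units(self):
        cfg = ModelConfig(score_net_layers=0, hidden_dim=1)
        params = ModelParams.initialize(cfg, 2)
        assert score(np.array([0.0]), cfg, params) == pytest.approx(0.5)
        assert score(np.array([1.0]), cfg, params) == pytest.approx(0.7310585786, abs=1e-9)
        assert score(np.array([40.0]), cfg, params) == pytest.approx(1.0, abs=1e-9)
        assert score(np.array([-40.0]), cfg, params) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_combination_units(self):
        assert combine_symmetric_logits(0.0, 0.0) == pytest.approx(0.5)
        assert combine_symmetric_logits(2.0, 0.0) == pytest.approx(0.7310585786, abs=1e-9)

    def test_symmetric_requires_declaration(self, default_graph):
        cfg = ModelConfig(seed=0)
        params = ModelParams.initialize(cfg, default_graph.num_relations)
        with pytest.raises(ValueError, match="symmetric"):
            score_symmetric(default_graph, 0, 1, 0, cfg, params)

    def test_batch_scores_match_individual(self, default_graph):
        from pathkg.model import QueryContext

        cfg = ModelConfig(seed=3)
        params = ModelParams.initialize(cfg, default_graph.num_relations)
        qs = [QueryContext(0, 6), QueryContext(5, 7), QueryContext(40, 6)]
        together = score_all_tails(default_graph, qs, cfg, params, batch_size=3)
        for i, q in enumerate(qs):
            alone = score_all_tails(default_graph, [q], cfg, params, batch_size=1)[0]
            np.testing.assert_allclose(together[i], alone, atol=1e-6)
        assert np.all((together > 0) & (together < 1))

    def test_deterministic_initialization_and_forward(self, default_graph):
        cfg = ModelConfig(seed=11)
        p1 = ModelParams.initialize(cfg, default_graph.num_relations)
        p2 = ModelParams.initialize(cfg, default_graph.num_relations)
        assert p1.checksum() == p2.checksum()
        t1, _ = forward(default_graph, [0], [6], cfg, p1)
        t2, _ = forward(default_graph, [0], [6], cfg, p2)
        np.testing.assert_array_equal(t1.states.data, t2.states.data)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        cfg = ModelConfig(seed=4, symmetric_relations=frozenset({1}))
        params = ModelParams.initialize(cfg, 4)
        save_checkpoint(tmp_path / "c.zip", cfg, params, extra={"note": "x"})
        cfg2, params2, extra = load_checkpoint(tmp_path / "c.zip")
        assert cfg2 == cfg
        assert extra == {"note": "x"}
        assert params2.checksum() == params.checksum()
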