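"""Ranking metrics against hand computations and brute-force oracles."""

import numpy as np
import pytest

from pathkg.evaluation import (
    RankedQuery,
    per_head_auprc,
    rank_of_positive,
    ranking_metrics,
    recall_curve_vs_random,
)


def brute_force_auprc(y: np.ndarray, s: np.ndarray) -> float:
    """Step-curve area via an explicit sweep over all distinct score thresholds."""
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    thresholds = sorted(set(s), reverse=True)
    total_pos = y.sum()
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        precision = tp / pred.sum()
        recall = tp / total_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def simple_query(scores, positives, filter_set=()):
    return RankedQuery(head=0, relation=0, scores=dict(scores), positives=set(positives), filter_set=set(filter_set))


class TestRankOfPositive:
    def test_top_scored_positive_is_rank_one(self):
        q = simple_query({1: 0.9, 2: 0.1, 3: 0.2}, {1})
        assert rank_of_positive(q, 1) == 1

    def test_tie_is_pessimistic(self):
        q = simple_query({1: 0.5, 2: 0.5}, {1})
        assert rank_of_positive(q, 1) == 2

    def test_filter_set_removes_competitor(self):
        q = simple_query({10: 0.9, 11: 0.8, 12: 0.7}, {12}, filter_set={10})
        assert rank_of_positive(q, 12) == 2

    def test_other_positives_removed_when_filtered(self):
        q = simple_query({1: 0.9, 2: 0.8, 3: 0.1}, {1, 3})
        assert rank_of_positive(q, 3) == 2  # positive 1 does not count against 3
        assert rank_of_positive(q, 3, filtered=False) == 3

    def test_filtered_never_worse_than_raw(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(3, 12)
            scores = {i: float(rng.uniform()) for i in range(n)}
            pos = set(rng.choice(n, size=rng.integers(1, n // 2 + 1), replace=False).tolist())
            filt = set(rng.choice(n, size=rng.integers(0, n // 2), replace=False).tolist()) - pos
            q = simple_query(scores, pos, filt)
            for p in pos:
                assert rank_of_positive(q, p) <= rank_of_positive(q, p, filtered=False)

    def test_unknown_positive_rejected(self):
        q = simple_query({1: 0.9}, {1})
        with pytest.raises(ValueError):
            rank_of_positive(q, 2)


class TestRankingMetrics:
    def test_hand_computed_fixture(self):
        # three single-positive queries with filtered ranks 1, 2 and 4
        queries = [
            simple_query({0: 0.9, 1: 0.5, 2: 0.3, 3: 0.2, 4: 0.1}, {0}),
            simple_query({0: 0.9, 1: 0.5, 2: 0.3, 3: 0.2, 4: 0.1}, {1}),
            simple_query({0: 0.9, 1: 0.5, 2: 0.3, 3: 0.2, 4: 0.1}, {3}),
        ]
        rep = ranking_metrics(queries, ks=[1, 3])
        assert rep.mr == pytest.approx(7 / 3, abs=1e-9)
        assert rep.mrr == pytest.approx((1 + 0.5 + 0.25) / 3, abs=1e-9)
        assert rep.hits_at[1] == pytest.approx(1 / 3, abs=1e-9)
        assert rep.hits_at[3] == pytest.approx(2 / 3, abs=1e-9)

    def test_perfect_ranking(self):
        queries = [simple_query({0: 0.9, 1: 0.1}, {0}) for _ in range(4)]
        rep = ranking_metrics(queries, ks=[1, 2])
        assert rep.mrr == 1.0 and rep.hits_at[1] == 1.0
        assert rep.ndcg_at[1] == 1.0 and rep.ndcg_at[2] == 1.0

    def test_multi_positive_precision_recall_ndcg(self):
        # positives at positions 1 and 3 of the ranked list
        q = simple_query({0: 0.9, 1: 0.8, 2: 0.7, 3: 0.1}, {0, 2})
        rep = ranking_metrics([q], ks=[2])
        assert rep.precision_at[2] == pytest.approx(0.5)
        assert rep.recall_at[2] == pytest.approx(0.5)
        ideal = 1.0 + 1.0 / np.log2(3)
        assert rep.ndcg_at[2] == pytest.approx(1.0 / ideal, abs=1e-9)

    def test_hits_and_recall_monotone_in_k(self):
        rng = np.random.default_rng(5)
        queries = []
        for _ in range(30):
            scores = {i: float(rng.uniform()) for i in range(10)}
            pos = set(rng.choice(10, size=2, replace=False).tolist())
            queries.append(simple_query(scores, pos))
        rep = ranking_metrics(queries, ks=[1, 2, 3, 5, 10])
        ks = [1, 2, 3, 5, 10]
        for a, b in zip(ks, ks[1:]):
            assert rep.hits_at[a] <= rep.hits_at[b]
            assert rep.recall_at[a] <= rep.recall_at[b]
        for q in queries:
            assert ranking_metrics([q], ks=[1]).precision_at[1] in (0.0, 1.0)

    def test_queries_without_positives_are_skipped_with_warning(self):
        queries = [simple_query({0: 0.5, 1: 0.2}, {0}), simple_query({0: 0.5, 1: 0.2}, set())]
        with pytest.warns(UserWarning, match="no positives"):
            rep = ranking_metrics(queries)
        assert rep.num_skipped == 1 and rep.num_queries == 1

    def test_flat_average_equals_per_query_for_single_positives(self):
        rng = np.random.default_rng(9)
        queries = []
        for _ in range(20):
            scores = {i: float(rng.uniform()) for i in range(8)}
            queries.append(simple_query(scores, {int(rng.integers(8))}))
        rep = ranking_metrics(queries)
        flat = np.mean([1.0 / rank_of_positive(q, next(iter(q.positives))) for q in queries])
        assert rep.mrr == pytest.approx(float(flat), abs=1e-12)


class TestPerHeadAUPRC:
    def test_perfect_separation(self):
        q = simple_query({0: 0.9, 1: 0.8, 2: 0.1, 3: 0.2}, {0, 1})
        assert per_head_auprc(q).auprc == pytest.approx(1.0)

    def test_degenerate_equal_scores_equals_prevalence(self):
        q = simple_query({0: 0.5, 1: 0.5, 2: 0.5, 3: 0.5}, {0})
        assert per_head_auprc(q).auprc == pytest.approx(0.25)

    def test_f1_and_specificity_fixture(self):
        q = simple_query({0: 0.9, 1: 0.8, 2: 0.1}, {0})
        hc = per_head_auprc(q)
        assert hc.f1 == pytest.approx(2 / 3, abs=1e-12)
        assert hc.specificity == pytest.approx(0.5, abs=1e-12)

    def test_no_positive_reported_missing(self):
        assert per_head_auprc(simple_query({0: 0.4, 1: 0.2}, set())) is None

    def test_matches_brute_force_threshold_sweep(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(4, 20))
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if y.all():
                y[0] = 0
            s = rng.choice(np.round(rng.uniform(size=6), 2), size=n)  # ties likely
            q = simple_query({i: float(s[i]) for i in range(n)}, {i for i in range(n) if y[i]})
            got = per_head_auprc(q)
            if got is None:
                continue
            assert got.auprc == pytest.approx(brute_force_auprc(y, s), abs=1e-9)


class TestRecallCurve:
    def test_threshold_extremes(self):
        preds = [((0, 1), 0.9), ((0, 2), 0.3)]
        rows = recall_curve_vs_random(preds, {(0, 1), (0, 2)}, [0.5], np.array([0.0, 0.95]))
        assert rows[0]["recall"] == 1.0
        assert rows[1]["recall"] == 0.0

    def test_any_relation_rule_uses_max(self):
        preds = [((0, 1), 0.2), ((0, 1), 0.8)]  # same pair, two relations
        rows = recall_curve_vs_random(preds, {(0, 1)}, [0.5], np.array([0.7]))
        assert rows[0]["recall"] == 1.0

    def test_separated_truth_vs_random_background(self):
        preds = [((i, i + 1), 0.9) for i in range(10)]
        truth = {(i, i + 1) for i in range(10)}
        rows = recall_curve_vs_random(preds, truth, [0.5] * 50, np.array([0.7]), n_resamples=200)
        assert rows[0]["recall"] == 1.0
        assert rows[0]["random_recall"] == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            recall_curve_vs_random([((0, 1), 0.5)], set(), [0.5], np.array([0.5]))
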