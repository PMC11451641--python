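"""Ranking evaluation for tail prediction: MR, MRR, Hits@k, NDCG@k,
Precision/Recall@k, per-head AUPRC/specificity/F1, and a recall-curve
comparison against a random baseline.

Protocol notes
--------------
*Filtered* ranking (the default) removes other known positives — from any
split — from the candidate list before ranking a positive, so a model is not
penalized for scoring a different true tail above the one being ranked; a raw
mode is available.  Ties are broken pessimistically: a positive tied with
negatives is ranked after all of them.  When an entity-type table is present,
candidates are restricted to entities of the true tail's type, matching the
type-aware training regime (switchable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score

from .kg_data import KnowledgeGraph, Triplet, UNKNOWN_TYPE

DEFAULT_KS = (1, 3, 10)


@dataclass
class RankedQuery:
    """Scored candidates for one (head, relation) query."""

    head: int
    relation: int
    scores: dict[int, float]
    positives: set[int]
    filter_set: set[int] = field(default_factory=set)

    def __post_init__(self):
        missing = self.positives - set(self.scores)
        if missing:
            raise ValueError(f"positives without scores: {sorted(missing)[:5]}")
        # a positive of this query must never be filtered away
        self.filter_set = set(self.filter_set) - self.positives


@dataclass
class HeadClassification:
    auprc: float
    specificity: float
    f1: float


@dataclass
class MetricReport:
    mr: float
    mrr: float
    hits_at: dict[int, float]
    ndcg_at: dict[int, float]
    precision_at: dict[int, float]
    recall_at: dict[int, float]
    per_head_auprc: dict[int, float]
    num_queries: int
    num_skipped: int

    def to_dict(self) -> dict:
        return {
            "mr": self.mr,
            "mrr": self.mrr,
            "hits_at": {str(k): v for k, v in self.hits_at.items()},
            "ndcg_at": {str(k): v for k, v in self.ndcg_at.items()},
            "precision_at": {str(k): v for k, v in self.precision_at.items()},
            "recall_at": {str(k): v for k, v in self.recall_at.items()},
            "num_queries": self.num_queries,
            "num_skipped": self.num_skipped,
        }


def rank_of_positive(query: RankedQuery, positive: int, filtered: bool = True) -> int:
    """1-based rank of `positive`, pessimistic ties, filtered by default.

    Filtered: candidates exclude the filter set and the query's *other*
    positives; the positive is placed after every equal-scored negative.
    """
    if positive not in query.positives:
        raise ValueError(f"{positive} is not a positive of this query")
    if positive not in query.scores:
        raise ValueError(f"positive {positive} has no score")
    s = query.scores[positive]
    excluded = (query.filter_set | (query.positives - {positive})) if filtered else set()
    rank = 1
    for cand, sc in query.scores.items():
        if cand == positive or cand in excluded:
            continue
        if sc >= s:
            rank += 1
    return rank


def _ranked_candidates(query: RankedQuery) -> list[int]:
    """Candidates (minus the cross-split filter set) sorted by score desc,
    positives after equal-scored negatives (pessimistic)."""
    cands = [c for c in query.scores if c not in query.filter_set]
    return sorted(cands, key=lambda c: (-query.scores[c], c in query.positives))


def _dcg(relevances: list[int], k: int) -> float:
    return sum(rel / np.log2(i + 2.0) for i, rel in enumerate(relevances[:k]))


def ranking_metrics(queries: list[RankedQuery], ks: list[int] = list(DEFAULT_KS)) -> MetricReport:
    """Aggregate the metric suite over queries.

    MR/MRR/Hits@k average over every (query, positive) pair using filtered
    ranks; NDCG@k (binary relevance, log2 discount), Precision@k and Recall@k
    are computed per query and macro-averaged.  Queries with no positives are
    skipped and counted.
    """
    if not ks or any(k < 1 for k in ks):
        raise ValueError("ks must be non-empty positive integers")
    ranks: list[int] = []
    ndcg = {k: [] for k in ks}
    prec = {k: [] for k in ks}
    rec = {k: [] for k in ks}
    auprc: dict[int, float] = {}
    skipped = 0
    for q in queries:
        if not q.positives:
            skipped += 1
            continue
        for pos in sorted(q.positives):
            ranks.append(rank_of_positive(q, pos))
        order = _ranked_candidates(q)
        rels = [1 if c in q.positives else 0 for c in order]
        npos = len(q.positives)
        for k in ks:
            hits_k = sum(rels[:k])
            prec[k].append(hits_k / k)
            rec[k].append(hits_k / npos)
            ideal = _dcg([1] * min(npos, k), k)
            ndcg[k].append(_dcg(rels, k) / ideal if ideal > 0 else 0.0)
        hc = per_head_auprc(q)
        if hc is not None:
            auprc[q.head] = hc.auprc
    if skipped:
        warnings.warn(f"{skipped} queries had no positives and were skipped")
    ranks_arr = np.asarray(ranks, dtype=np.float64)
    n = len(queries) - skipped
    return MetricReport(
        mr=float(ranks_arr.mean()) if len(ranks_arr) else float("nan"),
        mrr=float((1.0 / ranks_arr).mean()) if len(ranks_arr) else float("nan"),
        hits_at={k: float((ranks_arr <= k).mean()) if len(ranks_arr) else float("nan") for k in ks},
        ndcg_at={k: float(np.mean(ndcg[k])) for k in ks} if n else {k: float("nan") for k in ks},
        precision_at={k: float(np.mean(prec[k])) for k in ks} if n else {k: float("nan") for k in ks},
        recall_at={k: float(np.mean(rec[k])) for k in ks} if n else {k: float("nan") for k in ks},
        per_head_auprc=auprc,
        num_queries=n,
        num_skipped=skipped,
    )


def per_head_auprc(query: RankedQuery, threshold: float = 0.5) -> HeadClassification | None:
    """AUPRC over this head's candidates plus specificity/F1 at `threshold`.

    The area follows the precision-recall step curve over all score
    thresholds.  Returns None (missing, not zero) when the query has no
    positive or no negative candidate.
    """
    cands = [c for c in query.scores if c not in query.filter_set]
    y = np.array([1 if c in query.positives else 0 for c in cands])
    s = np.array([query.scores[c] for c in cands], dtype=np.float64)
    if y.sum() == 0 or y.sum() == len(y):
        return None
    auprc = float(average_precision_score(y, s))
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return HeadClassification(auprc=auprc, specificity=spec, f1=f1)


def recall_curve_vs_random(
    predictions: list[tuple[tuple[int, int], float]],
    truth: set[tuple[int, int]],
    background: list[float],
    thresholds: np.ndarray,
    n_resamples: int = 100,
    seed: int = 0,
) -> list[dict]:
    """Recall of true pairs above each threshold versus a resampled baseline.

    A pair counts as predicted when *any* relation's probability reaches the
    threshold, so predictions are first max-reduced per pair.  The random
    baseline assigns each truth pair a probability drawn from `background`
    (scores of triples overlapping the training set) and averages recall over
    `n_resamples` draws.
    """
    if not truth:
        raise ValueError("truth set must be non-empty")
    if not len(background):
        raise ValueError("background distribution must be non-empty")
    best: dict[tuple[int, int], float] = {}
    for pair, p in predictions:
        best[pair] = max(best.get(pair, -np.inf), p)
    missing = truth - set(best)
    if missing:
        raise ValueError(f"{len(missing)} truth pairs have no prediction")
    truth_probs = np.array([best[p] for p in sorted(truth)])
    rng = np.random.default_rng(seed)
    bg = np.asarray(background, dtype=np.float64)
    draws = rng.choice(bg, size=(n_resamples, len(truth_probs)), replace=True)
    rows = []
    for t in np.asarray(thresholds, dtype=np.float64):
        rows.append(
            {
                "threshold": float(t),
                "recall": float(np.mean(truth_probs >= t)),
                "random_recall": float(np.mean(draws >= t)),
            }
        )
    return rows


# -- model-facing driver -----------------------------------------------------


def build_queries(
    graph: KnowledgeGraph,
    probs: np.ndarray,
    triplets: list[Triplet],
    query_index: dict[tuple[int, int], int],
    restrict_by_type: bool = True,
) -> list[RankedQuery]:
    """Assemble RankedQuery objects from a (num_queries, num_nodes) score array."""
    known_all = graph.known_tails("all")
    by_query: dict[tuple[int, int], set[int]] = {}
    for t in triplets:
        by_query.setdefault((t.head, t.relation), set()).add(t.tail)
    vocab = graph.vocab
    typed = restrict_by_type and (vocab.types - {UNKNOWN_TYPE})
    queries = []
    for (h, r), positives in by_query.items():
        row = probs[query_index[(h, r)]]
        if typed:
            tail_type = vocab.type_of(next(iter(positives)))
            cands = vocab.ids_of_type(tail_type)
        else:
            cands = range(graph.num_nodes)
        scores = {c: float(row[c]) for c in cands}
        filt = (known_all.get((h, r), set()) - positives) & set(scores)
        queries.append(RankedQuery(head=h, relation=r, scores=scores, positives=set(positives), filter_set=filt))
    return queries


def evaluate_tail_prediction(
    graph: KnowledgeGraph,
    config,
    params,
    split: str = "test",
    triplets: list[Triplet] | None = None,
    ks: list[int] = list(DEFAULT_KS),
    restrict_by_type: bool = True,
    batch_size: int = 64,
) -> MetricReport:
    """Score all tails for each query of a split and run the metric suite."""
    from .model import QueryContext, score_all_tails

    if triplets is None:
        triplets = getattr(graph, split)
    if not triplets:
        nan_ks = {k: float("nan") for k in ks}
        return MetricReport(float("nan"), float("nan"), dict(nan_ks), dict(nan_ks), dict(nan_ks), dict(nan_ks), {}, 0, 0)
    pairs = sorted({(t.head, t.relation) for t in triplets})
    query_index = {pr: i for i, pr in enumerate(pairs)}
    contexts = [QueryContext(source=h, query_relation=r) for h, r in pairs]
    probs = score_all_tails(graph, contexts, config, params, batch_size=batch_size)
    queries = build_queries(graph, probs, triplets, query_index, restrict_by_type=restrict_by_type)
    return ranking_metrics(queries, ks=ks)
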