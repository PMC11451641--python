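"""Supervised training: type-aware negative sampling, NLL loss, early stopping.

Each positive triplet (u, r, v) is a tail-prediction query; one forward pass
scores every candidate tail, and the loss contrasts the positive tail against
n corrupted tails:

    L = -log p(v | u, r) - (1/n) * sum_i log(1 - p(v'_i | u, r))

Head prediction is covered by training the reverse relation: the train split
already contains (v, r⁻¹, u) for every (u, r, v), so only tails are ever
corrupted.  When type-aware sampling is on, corrupted tails are drawn only
from entities sharing the true tail's type — the sample space shrinks to the
plausible candidates and negatives become genuinely hard.  Candidates that
form a known train positive for the same (head, relation) are excluded
(filtered negatives); background (message-passing-only) edges neither supply
nor constrain candidates.  Negatives are resampled for every batch in every
epoch.

Model selection: validation MRR after each epoch, keeping the best checkpoint
(patience-based early stopping).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .evaluation import evaluate_tail_prediction
from .kg_data import KnowledgeGraph, Triplet, TypedEntityVocab, UNKNOWN_TYPE
from .model import ModelConfig, ModelParams, forward, score_logits

_CLAMP = np.finfo(float).eps


class SamplingError(RuntimeError):
    """No eligible negative candidate exists for a positive triplet."""


@dataclass(frozen=True)
class NegativeSamplingConfig:
    num_negatives: int = 16
    type_aware: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if self.num_negatives < 1:
            raise ValueError("num_negatives must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 64
    learning_rate: float = 1e-2
    patience: int = 8
    seed: int = 0
    # model selection metric is fixed: validation MRR

    def __post_init__(self):
        for name in ("epochs", "batch_size", "learning_rate", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class NegativeSampler:
    """Draws corrupted tails for positives, with replacement, filtered.

    Pools are precomputed per entity type; per (head, relation) the known
    train tails (including the positive itself) are removed before drawing.
    """

    def __init__(self, graph: KnowledgeGraph, vocab: TypedEntityVocab, cfg: NegativeSamplingConfig):
        self.cfg = cfg
        self.vocab = vocab
        self.known = graph.known_tails("train")
        if cfg.type_aware:
            self.pools = {t: np.array(vocab.ids_of_type(t), dtype=np.int64) for t in vocab.types}
        else:
            self.all_ids = np.arange(len(vocab), dtype=np.int64)
        self.rng = np.random.default_rng(cfg.rng_seed)

    def sample(self, positive: Triplet, rng: np.random.Generator | None = None) -> list[int]:
        rng = rng or self.rng
        if self.cfg.type_aware:
            tail_type = self.vocab.type_of(positive.tail)
            if tail_type == UNKNOWN_TYPE:
                raise TypeError(f"type-aware sampling needs a typed tail; entity {positive.tail} is untyped")
            pool = self.pools[tail_type]
        else:
            pool = self.all_ids
        excluded = self.known.get((positive.head, positive.relation), {positive.tail})
        eligible = pool[~np.isin(pool, list(excluded))]
        if eligible.size == 0:
            kind = self.vocab.type_of(positive.tail) if self.cfg.type_aware else "any"
            raise SamplingError(f"no eligible negative candidates of type {kind!r} for {positive}")
        return list(rng.choice(eligible, size=self.cfg.num_negatives, replace=True))


def sample_negatives(
    positive: Triplet,
    vocab: TypedEntityVocab,
    graph: KnowledgeGraph,
    cfg: NegativeSamplingConfig,
) -> list[int]:
    """One-off negative draw for a single positive (see :class:`NegativeSampler`)."""
    return NegativeSampler(graph, vocab, cfg).sample(positive)


def nll_loss(p_pos: float, p_negs: list[float]) -> float:
    """Negative log-likelihood of one positive against its n negatives."""
    if len(p_negs) == 0:
        raise ValueError("at least one negative probability is required")
    p_pos = min(max(float(p_pos), _CLAMP), 1.0 - _CLAMP)
    negs = np.clip(np.asarray(p_negs, dtype=np.float64), _CLAMP, 1.0 - _CLAMP)
    return float(-np.log(p_pos) - np.mean(np.log(1.0 - negs)))


class Adam:
    """Adam with bias correction; operates on the autodiff parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


@dataclass
class TrainResult:
    params: ModelParams
    config: ModelConfig
    log: list[dict]
    best_epoch: int
    best_valid_mrr: float


def _batch_loss(
    graph: KnowledgeGraph,
    batch: list[Triplet],
    negatives: list[list[int]],
    config: ModelConfig,
    params: ModelParams,
) -> Tensor:
    heads = np.array([t.head for t in batch])
    rels = np.array([t.relation for t in batch])
    pos = np.array([t.tail for t in batch])
    table, _ = forward(graph, heads, rels, config, params)
    logits = score_logits(table.states, config, params)  # (B, N)
    p = logits.sigmoid().clip(_CLAMP, 1.0 - _CLAMP)
    B = len(batch)
    n = len(negatives[0])
    rows = np.repeat(np.arange(B), n)
    neg_idx = np.concatenate([np.asarray(ns) for ns in negatives])
    p_pos = p[np.arange(B), pos]
    p_neg = p[rows, neg_idx].reshape(B, n)
    return (-(p_pos.log()) - (1.0 - p_neg).log().mean(axis=1)).mean()


def train(
    graph: KnowledgeGraph,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    neg_cfg: NegativeSamplingConfig,
    log_path: str | Path | None = None,
    eval_batch_size: int = 64,
) -> TrainResult:
    """Fit the model on the train split, selecting on validation MRR.

    Returns the parameters of the best-validation epoch, with a JSON-lines
    style per-epoch log (train loss, validation MRR, best flag).
    """
    params = ModelParams.initialize(model_cfg, graph.num_relations)
    sampler = NegativeSampler(graph, graph.vocab, neg_cfg)
    opt = Adam(params.parameters(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)

    triplets = list(graph.train)
    log: list[dict] = []
    best = {"mrr": -1.0, "epoch": -1, "data": params.copy_data()}
    stale = 0
    for epoch in range(1, train_cfg.epochs + 1):
        order = rng.permutation(len(triplets))
        losses = []
        for lo in range(0, len(order), train_cfg.batch_size):
            batch = [triplets[i] for i in order[lo : lo + train_cfg.batch_size]]
            negatives = [sampler.sample(t, rng) for t in batch]
            opt.zero_grad()
            loss = _batch_loss(graph, batch, negatives, model_cfg, params)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}, batch {lo // train_cfg.batch_size}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        report = evaluate_tail_prediction(
            graph, model_cfg, params, split="valid", batch_size=eval_batch_size
        )
        valid_mrr = report.mrr
        # with no validation split, keep the final epoch (nothing to select on)
        improved = valid_mrr > best["mrr"] or np.isnan(valid_mrr)
        if improved:
            best = {"mrr": valid_mrr, "epoch": epoch, "data": params.copy_data()}
            stale = 0
        else:
            stale += 1
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)) if losses else float("nan"),
                "valid_mrr": valid_mrr,
                "best_so_far": best["mrr"],
            }
        )
        if stale > train_cfg.patience:
            break

    params.load_data(best["data"])
    if log_path is not None:
        with open(log_path, "w", encoding="utf-8") as fh:
            for rec in log:
                fh.write(json.dumps(rec) + "\n")
    return TrainResult(params=params, config=model_cfg, log=log, best_epoch=best["epoch"], best_valid_mrr=best["mrr"])
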