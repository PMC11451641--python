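"""Learned relaxation of the generalized Bellman-Ford recursion.

The model computes, for one query (source entity u, query relation q), a
conditional representation h_q(u, v) for every candidate tail v by T rounds of
relational message passing over the propagation graph (supervision train edges
plus any background regulatory edges):

* layer 0 — an indicator places the learned query-relation embedding q on the
  source node and the zero vector everywhere else;
* each layer — every node aggregates, over its incoming edges (x, r, v), the
  message combining the neighbour state h_x with a relation weight
  w_q(x, r, v); the layer-0 boundary state is always part of the aggregated
  multiset, mirroring the boundary re-injection of the exact recursion;
* the link probability is p(v | u, q) = sigmoid(f(h_q(u, v))) with f a small
  feed-forward network.

Relation weights w_q are a per-relation linear function of the query
embedding: they depend on (r, q) only, never on the endpoints.  Message
operators follow the classic KG-embedding algebra — translation (h + w),
multiplication (h * w) and rotation (complex product with a unit-modulus w
parameterized by phases).  Aggregation is sum, mean, max, or principal
neighborhood aggregation (PNA: mean/max/min/std scaled by degree scalers and
linearly projected).

A degenerate configuration (1-dim states, multiplication message, sum
aggregation, no normalization, identity readout, fixed edge weights)
reproduces the exact sum-product Bellman-Ford and is pinned as a test.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass
from io import BytesIO
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .kg_data import KnowledgeGraph

MESSAGE_OPS = ("translation", "multiplication", "rotation")
AGGREGATIONS = ("sum", "mean", "max", "pna")
CHECKPOINT_SCHEMA = "pathkg-checkpoint-v1"
_LN_EPS = 1e-5


@dataclass(frozen=True)
class ModelConfig:
    layers: int = 2
    hidden_dim: int = 16
    message_op: str = "multiplication"
    aggregation: str = "sum"
    score_net_layers: int = 2
    seed: int = 0
    layer_norm: bool = True
    use_relu: bool = True
    symmetric_relations: frozenset = frozenset()

    def __post_init__(self):
        if self.layers < 0 or self.hidden_dim < 1 or self.score_net_layers < 0:
            raise ValueError("layers, hidden_dim must be positive")
        if self.message_op not in MESSAGE_OPS:
            raise ValueError(f"message_op must be one of {MESSAGE_OPS}, got {self.message_op!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}, got {self.aggregation!r}")
        if self.message_op == "rotation" and self.hidden_dim % 2:
            raise ValueError("rotation interprets state pairs as complex components; hidden_dim must be even")


@dataclass(frozen=True)
class QueryContext:
    """One conditional query: source entity u and query relation q."""

    source: int
    query_relation: int


@dataclass
class PairStateTable:
    """Per-layer conditional states h_q^(t)(u, v) for all v, batched over queries."""

    states: Tensor  # (num_queries, num_nodes, hidden_dim)
    layer: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.states.data)):
            raise FloatingPointError(f"non-finite pair states at layer {self.layer}")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class ModelParams:
    """All learnable tensors, keyed by name.

    One relation-weight block (matrix + bias) per augmented relation id, a
    query-relation embedding table, per-layer layer-norm affine parameters,
    the optional PNA projection and the scoring network f.
    """

    def __init__(self, tensors: dict[str, Tensor]):
        self.tensors = tensors

    def __getitem__(self, key: str) -> Tensor:
        return self.tensors[key]

    def parameters(self) -> list[Tensor]:
        return list(self.tensors.values())

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.zero_grad()

    def copy_data(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.tensors.items()}

    def load_data(self, datas: dict[str, np.ndarray]) -> None:
        for k, arr in datas.items():
            self.tensors[k].data = arr.copy()

    def checksum(self) -> float:
        """Order-stable scalar digest of all parameters (determinism checks)."""
        return float(sum(np.sum(t.data) for t in self.tensors.values()))

    @classmethod
    def initialize(cls, config: ModelConfig, num_relations: int) -> "ModelParams":
        rng = np.random.default_rng(config.seed)
        d, R2 = config.hidden_dim, num_relations
        t: dict[str, Tensor] = {}
        t["query_emb"] = Tensor(_glorot(rng, R2, d, (R2, d)), requires_grad=True)
        t["rel_w"] = Tensor(_glorot(rng, d, d, (d, R2 * d)), requires_grad=True)
        t["rel_b"] = Tensor(_glorot(rng, R2, d, (R2, d)), requires_grad=True)
        for layer in range(config.layers):
            t[f"ln_scale_{layer}"] = Tensor(np.ones(d), requires_grad=True)
            t[f"ln_shift_{layer}"] = Tensor(np.zeros(d), requires_grad=True)
        if config.aggregation == "pna":
            t["pna_w"] = Tensor(_glorot(rng, 12 * d, d, (12 * d, d)), requires_grad=True)
            t["pna_b"] = Tensor(np.zeros(d), requires_grad=True)
        dims = [d] * config.score_net_layers + [1]
        for i in range(config.score_net_layers):
            t[f"score_w_{i}"] = Tensor(_glorot(rng, dims[i], dims[i + 1], (dims[i], dims[i + 1])), requires_grad=True)
            t[f"score_b_{i}"] = Tensor(np.zeros(dims[i + 1]), requires_grad=True)
        return cls(t)


# -- the three primitive operations -----------------------------------------


def indicator(source: int, query_embedding: np.ndarray, num_nodes: int) -> PairStateTable:
    """Layer-0 boundary: query embedding on the source row, zeros elsewhere."""
    if not 0 <= source < num_nodes:
        raise IndexError(f"source {source} out of range for {num_nodes} nodes")
    q = np.asarray(query_embedding, dtype=np.float64)
    states = np.zeros((1, num_nodes, q.shape[-1]))
    states[0, source] = q
    return PairStateTable(states=Tensor(states), layer=0)


def message(h_x: Tensor, w: Tensor, op: str) -> Tensor:
    """Combine a neighbour state with a relation weight.

    translation: h + w; multiplication: h ∘ w; rotation: elementwise complex
    product of h (first half real parts, second half imaginary) with the
    unit-modulus complex number of phase w (first half of w are the angles).
    """
    h_x = h_x if isinstance(h_x, Tensor) else Tensor(h_x)
    w = w if isinstance(w, Tensor) else Tensor(w)
    if h_x.shape[-1] != w.shape[-1]:
        raise ValueError(f"state/weight length mismatch: {h_x.shape[-1]} vs {w.shape[-1]}")
    if op == "translation":
        return h_x + w
    if op == "multiplication":
        return h_x * w
    if op == "rotation":
        d = h_x.shape[-1]
        if d % 2:
            raise ValueError("rotation requires an even dimension")
        half = d // 2
        idx = (Ellipsis,)
        re, im = h_x[idx + (slice(None, half),)], h_x[idx + (slice(half, None),)]
        theta = w[idx + (slice(None, half),)]
        cos_t, sin_t = theta.cos(), theta.sin()
        return concat([re * cos_t - im * sin_t, re * sin_t + im * cos_t], axis=h_x.ndim - 1)
    raise ValueError(f"unknown message op {op!r}")


def degree_statistics(graph: KnowledgeGraph) -> float:
    """Mean log(in-degree + 1) of the propagation graph — the PNA scale delta."""
    _, _, dst = graph.edge_arrays()
    deg = np.bincount(dst, minlength=graph.num_nodes).astype(np.float64)
    return float(np.mean(np.log(deg + 1.0))) or 1.0


def aggregate(
    messages: list[np.ndarray],
    boundary: np.ndarray,
    mode: str,
    degree_stats: float | None = None,
    pna_proj: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Permutation-invariant reduction of messages ∪ {boundary} for one node.

    The vectorized model path reduces over edges via segment operations; this
    is the reference single-node form.  An empty message list reduces to the
    boundary alone.
    """
    rows = np.asarray(list(messages) + [np.asarray(boundary, dtype=np.float64)])
    if mode == "sum":
        return rows.sum(axis=0)
    if mode == "mean":
        return rows.mean(axis=0)
    if mode == "max":
        return rows.max(axis=0)
    if mode == "pna":
        if degree_stats is None or pna_proj is None:
            raise ValueError("pna requires degree statistics and a projection")
        stats = np.concatenate([rows.mean(0), rows.max(0), rows.min(0), rows.std(0)])
        deg = np.log(rows.shape[0] + 1.0)
        amp, att = deg / degree_stats, degree_stats / deg
        w, b = pna_proj
        return np.concatenate([stats, stats * amp, stats * att]) @ w + b
    raise ValueError(f"unknown aggregation {mode!r}")


# -- the full propagation ----------------------------------------------------


def _layer_norm(h: Tensor, scale: Tensor, shift: Tensor) -> Tensor:
    m = h.mean(axis=-1, keepdims=True)
    centered = h - m
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + _LN_EPS).sqrt() * scale + shift


def forward(
    graph: KnowledgeGraph,
    sources: np.ndarray,
    query_relations: np.ndarray,
    config: ModelConfig,
    params: ModelParams,
    edge_weights: np.ndarray | None = None,
    capture_edge_weights: bool = False,
) -> tuple[PairStateTable, Tensor | None]:
    """Propagate T layers for a batch of queries; returns the layer-T table.

    `edge_weights` (shape (num_edges, hidden_dim)) bypasses the learned
    relation-weight head — used by the exact-recursion equivalence checks.
    With `capture_edge_weights` the per-edge weights become an independent
    gradient leaf (shared across layers), returned as the second element; the
    explanation module differentiates predictions against it.
    """
    src, rel, dst = graph.edge_arrays()
    N, d = graph.num_nodes, config.hidden_dim
    sources = np.atleast_1d(np.asarray(sources, dtype=np.int64))
    query_relations = np.atleast_1d(np.asarray(query_relations, dtype=np.int64))
    B = sources.shape[0]
    if sources.max(initial=0) >= N:
        raise IndexError("source id out of range")

    q = params["query_emb"].gather_rows(query_relations)  # (B, d)
    onehot = np.zeros((B, N, 1))
    onehot[np.arange(B), sources, 0] = 1.0
    boundary = q.reshape(B, 1, d) * Tensor(onehot)  # (B, N, d) indicator

    if edge_weights is not None:
        w_edge = Tensor(np.broadcast_to(np.asarray(edge_weights, dtype=np.float64), (B, len(src), d)).copy())
    else:
        w_flat = q @ params["rel_w"]  # (B, 2R*d)
        w_all = w_flat.reshape(B, -1, d) + params["rel_b"]
        w_edge = w_all.gather_rows(rel, axis=1)  # (B, E, d)
    leaf = None
    if capture_edge_weights:
        leaf = Tensor(w_edge.data.copy(), requires_grad=True)
        w_edge = leaf

    dst_full = np.concatenate([dst, np.arange(N, dtype=np.int64)])
    counts = np.bincount(dst_full, minlength=N).astype(np.float64)  # in-degree + 1
    delta = degree_statistics(graph) if config.aggregation == "pna" else None

    h = boundary
    for layer in range(config.layers):
        h_src = h.gather_rows(src, axis=1)  # (B, E, d)
        msgs = message(h_src, w_edge, config.message_op)
        # the boundary joins the aggregated multiset at every layer, as one
        # virtual self-message per node
        msgs_full = concat([msgs, boundary], axis=1)
        h = _aggregate_segments(msgs_full, dst_full, N, counts, config, params, delta)
        if config.layer_norm:
            h = _layer_norm(h, params[f"ln_scale_{layer}"], params[f"ln_shift_{layer}"])
        if config.use_relu:
            h = h.relu()
        if not np.all(np.isfinite(h.data)):
            raise FloatingPointError(f"non-finite states after layer {layer + 1}")
    return PairStateTable(states=h, layer=config.layers), leaf


def _aggregate_segments(
    msgs: Tensor,
    dst: np.ndarray,
    num_nodes: int,
    counts: np.ndarray,
    config: ModelConfig,
    params: ModelParams,
    delta: float | None,
) -> Tensor:
    mode = config.aggregation
    if mode == "sum":
        return msgs.scatter_add(dst, num_nodes, axis=1)
    if mode == "mean":
        return msgs.scatter_add(dst, num_nodes, axis=1) * Tensor(1.0 / counts[:, None])
    if mode == "max":
        return msgs.segment_max(dst, num_nodes, axis=1)
    # pna
    inv = Tensor(1.0 / counts[:, None])
    mean = msgs.scatter_add(dst, num_nodes, axis=1) * inv
    sq_mean = (msgs * msgs).scatter_add(dst, num_nodes, axis=1) * inv
    std = ((sq_mean - mean * mean).relu() + 1e-10).sqrt()
    mx = msgs.segment_max(dst, num_nodes, axis=1)
    mn = -((-msgs).segment_max(dst, num_nodes, axis=1))
    stats = concat([mean, mx, mn, std], axis=2)  # (B, N, 4d)
    log_deg = np.log(counts + 1.0)
    amp = (log_deg / delta)[:, None]
    att = (delta / np.maximum(log_deg, 1e-6))[:, None]
    full = concat([stats, stats * Tensor(amp), stats * Tensor(att)], axis=2)
    return full @ params["pna_w"] + params["pna_b"]


# -- scoring -----------------------------------------------------------------


def score_logits(states: Tensor, config: ModelConfig, params: ModelParams) -> Tensor:
    """Feed-forward readout f: (B, N, d) states -> (B, N) logits.

    With ``score_net_layers == 0`` the readout is the component sum (identity
    in one dimension) — the configuration used by the exact-recursion checks.
    """
    if config.score_net_layers == 0:
        return states.sum(axis=-1)
    h = states
    for i in range(config.score_net_layers):
        h = h @ params[f"score_w_{i}"] + params[f"score_b_{i}"]
        if i < config.score_net_layers - 1:
            h = h.relu()
    return h.reshape(h.shape[0], h.shape[1])


def score(pair_state: Tensor | np.ndarray, config: ModelConfig, params: ModelParams) -> float:
    """p(v | u, q) = sigmoid(f(h_q(u, v))) for a single pair state vector."""
    t = pair_state if isinstance(pair_state, Tensor) else Tensor(pair_state)
    logits = score_logits(t.reshape(1, 1, t.shape[-1]), config, params)
    return float(logits.sigmoid().data[0, 0])


def combine_symmetric_logits(f_forward: float, f_reverse: float) -> float:
    """Symmetric-relation score: sigmoid of the mean of the two direction logits."""
    z = 0.5 * (float(f_forward) + float(f_reverse))
    return float(1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))))


def score_symmetric(
    graph: KnowledgeGraph,
    u: int,
    v: int,
    query_relation: int,
    config: ModelConfig,
    params: ModelParams,
) -> float:
    """Score an undirected relation by averaging forward and reverse-query logits.

    Both terms condition on source u: the first under the query relation q,
    the second under its inverse q⁻¹.  The relation must be declared symmetric
    in the model configuration.
    """
    if query_relation not in config.symmetric_relations:
        raise ValueError(f"relation {query_relation} not declared symmetric in ModelConfig")
    q_inv = graph.relations.inverse_of(query_relation)
    table, _ = forward(graph, np.array([u, u]), np.array([query_relation, q_inv]), config, params)
    logits = score_logits(table.states, config, params).data
    return combine_symmetric_logits(logits[0, v], logits[1, v])


def score_all_tails(
    graph: KnowledgeGraph,
    queries: list[QueryContext],
    config: ModelConfig,
    params: ModelParams,
    batch_size: int = 64,
) -> np.ndarray:
    """Probabilities p(v | u, q) for every node v, per query; (len(queries), N)."""
    out = np.zeros((len(queries), graph.num_nodes))
    for lo in range(0, len(queries), batch_size):
        chunk = queries[lo : lo + batch_size]
        table, _ = forward(
            graph,
            np.array([c.source for c in chunk]),
            np.array([c.query_relation for c in chunk]),
            config,
            params,
        )
        logits = score_logits(table.states, config, params)
        out[lo : lo + len(chunk)] = logits.sigmoid().data
    return out


# -- checkpointing -----------------------------------------------------------


def save_checkpoint(path: str | Path, config: ModelConfig, params: ModelParams, extra: dict | None = None) -> None:
    """Write a single-file archive: config JSON + parameter arrays."""
    cfg = {k: (sorted(v) if isinstance(v, frozenset) else v) for k, v in vars(config).items()}
    meta = {"schema": CHECKPOINT_SCHEMA, "config": cfg, "extra": extra or {}}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        buf = BytesIO()
        np.savez(buf, **{k: t.data for k, t in params.tensors.items()})
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[ModelConfig, ModelParams, dict]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta.get('schema')!r}")
        cfg_dict = meta["config"]
        cfg_dict["symmetric_relations"] = frozenset(cfg_dict.get("symmetric_relations", ()))
        config = ModelConfig(**cfg_dict)
        arrays = np.load(BytesIO(zf.read("params.npz")))
        tensors = {k: Tensor(arrays[k], requires_grad=True) for k in arrays.files}
    return config, ModelParams(tensors), meta.get("extra", {})
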