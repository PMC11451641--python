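"""Exact generalized Bellman-Ford over an abstract semiring.

The path formulation behind the learned model: for a fixed source u, the
quantity attached to every node v is the generalized sum (⊕) over paths
u→v of the generalized product (⊗) of edge weights along the path.  With
(min, +) this is single-source shortest paths; with (+, ×) it is the sum
over paths of products of edge weights.  The recursion

    h^(0)(v) = one  if v == source else zero
    h^(t)(v) = [ ⊕ over incoming (x, r, v) of  h^(t-1)(x) ⊗ w(x, r, v) ] ⊕ h^(0)(v)

re-injects the boundary term at every layer, which is exactly the update the
neural relaxation mirrors; the tests pin the consequences of that choice.

This module is deliberately scalar and slow — it is the verifiable oracle the
neural layers are checked against, not a production path engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .kg_data import KnowledgeGraph, Triplet

MAX_BRUTE_FORCE_LEN = 6


@dataclass(frozen=True)
class Semiring:
    """An (⊕, ⊗) algebra with identities `zero` (of ⊕) and `one` (of ⊗)."""

    aggregate: Callable[[float, float], float]
    combine: Callable[[float, float], float]
    zero: float
    one: float

    def agg_many(self, values) -> float:
        out = self.zero
        for v in values:
            out = self.aggregate(out, v)
        return out


MIN_PLUS = Semiring(aggregate=min, combine=lambda a, b: a + b, zero=math.inf, one=0.0)
SUM_PRODUCT = Semiring(aggregate=lambda a, b: a + b, combine=lambda a, b: a * b, zero=0.0, one=1.0)


def generalized_bellman_ford(
    graph: KnowledgeGraph,
    source: int,
    edge_weight: dict[Triplet, float],
    ring: Semiring,
    iterations: int,
) -> dict[int, float]:
    """Run `iterations` synchronous Bellman-Ford updates from `source`.

    Returns the full node -> value table h^(T).  Every propagation edge must
    have a weight; self-loops participate as ordinary edges.
    """
    if iterations < 0:
        raise ValueError(f"iterations must be >= 0, got {iterations}")
    for e in graph.propagation_edges:
        if e not in edge_weight:
            raise KeyError(f"no weight defined for propagation edge {e}")

    nodes = range(graph.num_nodes)
    boundary = {v: (ring.one if v == source else ring.zero) for v in nodes}
    h = dict(boundary)
    for _ in range(iterations):
        # synchronous (Jacobi) update: h_new from h only
        h_new = {}
        for v in nodes:
            acc = ring.zero
            for e in graph.incoming(v):
                acc = ring.aggregate(acc, ring.combine(h[e.head], edge_weight[e]))
            h_new[v] = ring.aggregate(acc, boundary[v])
        h = h_new
    return h


def _all_paths(graph: KnowledgeGraph, source: int, target: int, max_len: int):
    """Yield every distinct edge-sequence path source→target with ≤ max_len edges."""
    if source == target:
        yield []
    stack: list[tuple[int, list[Triplet]]] = [(source, [])]
    while stack:
        node, path = stack.pop()
        if len(path) >= max_len:
            continue
        for e in graph.propagation_edges:
            if e.head != node:
                continue
            new_path = path + [e]
            if e.tail == target:
                yield new_path
            stack.append((e.tail, new_path))


def brute_force_path_sum(
    graph: KnowledgeGraph,
    source: int,
    target: int,
    edge_weight: dict[Triplet, float],
    ring: Semiring,
    max_len: int,
) -> float:
    """⊕ over all source→target edge-sequences of length ≤ max_len of the ⊗-product.

    Exponential-time enumeration guarded at ``max_len <= 6``; on DAGs with
    T = longest path length this coincides with the recursion and serves as
    its independent oracle.
    """
    if max_len > MAX_BRUTE_FORCE_LEN:
        raise ValueError(f"max_len {max_len} exceeds brute-force guard {MAX_BRUTE_FORCE_LEN}")
    acc = ring.zero
    for path in _all_paths(graph, source, target, max_len):
        w = ring.one
        for e in path:
            w = ring.combine(w, edge_weight[e])
        acc = ring.aggregate(acc, w)
    return acc
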