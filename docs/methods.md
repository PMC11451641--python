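# Methods

## Model

`pathkg` scores a candidate link (u, q, v) from a conditional pair
representation h_q(u, v) computed by T rounds of relational message passing
over the propagation graph. The computation is the neural relaxation of the
generalized Bellman-Ford recursion: layer 0 places the learned embedding of
the query relation q on the source node u (zeros elsewhere); each layer
aggregates, per node, the messages from incoming edges together with the
node's layer-0 boundary state; the final state is mapped to a probability by
a feed-forward readout and a sigmoid. Including the boundary in every
layer's aggregated multiset (rather than only at t = 0) mirrors the printed
recursion of the exact algorithm; the consequence for path counting — a
length-l path contributes at every T ≥ l — is pinned by tests that compare
against brute-force path enumeration.

Assumptions worth making explicit:

* **Edge weights depend on (r, q) only.** w_q(x, r, v) is a per-relation
  affine function of the query embedding, independent of the endpoints.
  Memory is O(R·d²) and the degenerate-configuration equivalence with the
  exact semiring core stays available.
* **Synchronous updates.** Layer t is computed wholly from layer t−1
  (Jacobi iteration), as the dynamic-programming formulation implies.
* **Self-loops and parallel edges** are ordinary edges: a self-loop
  participates in every layer, and parallel edges with different relations
  are distinct (also as paths in explanations).
* **Reverse closure.** Every relation r gets an inverse r⁻¹ (id r + R) and
  every propagation edge a reverse counterpart, so head prediction is tail
  prediction under the reverse query. Datasets that already ship both
  directions can be cleaned with `strip_preexisting_reverse`.

## Exact semiring core

`pathkg.semiring` implements the recursion over an abstract (⊕, ⊗) algebra
in scalar double precision, with (min, +) and (+, ×) instances, plus a
brute-force enumeration of all paths up to length 6. It exists as the
verifiable skeleton the neural model is checked against: with 1-dim states,
multiplication messages, sum aggregation, identity readout, no layer norm or
ReLU, and fixed edge weights, `forward` reproduces the (+, ×) recursion to
machine precision. It is not a general semiring library.

## Parameters and defaults

| parameter | default | notes |
|---|---|---|
| layers T | 2 | path length the model can exploit; matches the 2-hop planted rules |
| hidden_dim d | 16 | per-node state width; rotation requires even d |
| message_op | multiplication | translation / multiplication / rotation (phases, unit modulus by construction) |
| aggregation | sum | sum / mean / max / PNA (mean,max,min,std × identity,amplification,attenuation scalers, learned projection) |
| score_net_layers | 2 | depth of the readout f; 0 = component sum (oracle configuration) |
| layer_norm, use_relu | on | switchable off; required off for the exact-equivalence configuration |
| num_negatives n | 16 | corrupted tails per positive, resampled every batch and epoch |
| type_aware | true | corrupt tails within the true tail's entity type |
| epochs / batch / lr / patience | 40 / 64 / 1e-2 / 8 | Adam; selection on validation MRR, best checkpoint kept |

Hyperparameters were chosen on the validation MRR of the seed-1 benchmark
bundle and then fixed for all experiments. Initialization is Glorot-uniform
from the model seed. PNA degree scalers use log(indegree + 1) normalized by
the mean log-degree of the propagation graph, computed once.

Negative pools exclude tails of known *train* positives for the same
(head, relation) — filtering avoids the most common false negatives without
touching held-out information. Background edges neither supply nor
constrain candidates. Only tails are corrupted; the reverse-relation
training covers head corruption.

## Evaluation protocol

Filtered ranking is the default: when ranking one positive, other known
positives of the same query (from any split) are removed from the candidate
list; a `--raw`/`filtered=False` switch gives the unfiltered rank, and the
filtered rank never exceeds it. Ties break pessimistically (the positive
ranks below every equal-scored negative). When a type table is present,
candidates are restricted to entities of the true tail's type, consistent
with type-aware training; this too is switchable. MR/MRR/Hits@k average
over (query, positive) pairs; NDCG@k (binary relevance, log2 discount),
Precision@k and Recall@k are macro-averaged per query; AUPRC (step-curve
area, with specificity and F1 at threshold 0.5) is computed per head and
checked against an explicit threshold sweep. The recall-curve helper
compares the recall of true pairs above a threshold — a pair counts if
*any* relation clears it — against a baseline that resamples probabilities
from a supplied background distribution.

## Explanations

Edge importance is the gradient of p(v | u, q) with respect to the edge's
message weight, one leaf tensor shared across layers, reduced by summing
components (L2 switchable). Edges on no source→tail path within T hops get
exactly zero. A path's importance is the sum of its edge importances —
signed; negative importances are kept, matching the linear-surrogate
framing — and the top-k paths are found by an exact k-best dynamic program
over layers (no beam pruning at the sizes this package targets). Analytic
importances agree with central finite differences to better than 1e-3
relative error, and the k-best extraction is tested against exhaustive
enumeration.

## Synthetic benchmark

The generator emulates the structure the model is designed for: typed
entities, premise relations, conclusions entailed by 2-hop compositional
rules, a configurable fraction of materialized conclusions, type-respecting
uniform noise, and a premise set routed to a background (message-passing
only) file. The default scenario — 4 types × 30 entities, premise
out-degree 2, two rules, 10% noise, 0.7/0.1/0.2 splits — trains a 2-layer
model in ~10 s on one core; that size was chosen so multi-seed paired
experiments complete in minutes. Noise edges on conclusion relations go to
the train split only, so every held-out test edge is rule-entailed with
witnessing chains recorded in the manifest. An ablation helper emits two
bundles with identical supervision and the background file present/absent.

What the generator does **not** emulate: realistic degree distributions
(real KGs are heavy-tailed; here out-degrees are near-uniform), entity
spaces dominated by background-only nodes (real graphs have 10³–10⁵× more
background entities than supervision tails), incomplete typing, and
confidence-scored edges beyond a uniform optional column. Passing the
planted-rule and ablation tests therefore demonstrates that the machinery
learns and explains compositional structure and that background message
passing carries real signal — not that performance numbers transfer to any
particular production KG.

### A known limitation: the type-aware sampling comparison at small scale

On this benchmark, paired type-aware vs type-free training does *not* show
a type-aware advantage (type-free wins most seeds by a small margin). The
cause is a pool-size artifact: with 30-entity type pools and ~4 entailed
conclusions per head, roughly one held-out true tail sits in every same-type
candidate pool, so type-restricted corruption samples exactly the entities
validation measures about four times as often as uniform corruption does,
and the resulting anti-signal flows through the shared relation weights.
The regime where type-aware sampling pays off — huge entity spaces in which
uniform corruption almost always draws a trivially off-type entity — is not
reachable at desk scale. The comparison is still computed and reported
honestly by the acceptance script (`type_aware_*` entries).

## Numerical choices

Double precision everywhere; logits clamped to ±500 before the sigmoid;
probabilities clamped at machine-epsilon margins inside the loss; layer-norm
epsilon 1e-5 (an all-zero state normalizes to the learned shift); max
aggregation splits subgradients evenly among ties; empty neighborhoods
reduce to the boundary state alone (never NaN). Training is single-threaded
and deterministic: identical seeds give identical parameter checksums.

## Design choices where the design was open

* Duplicate triplets are removed after reading, before reverse
  augmentation; background edges are reverse-augmented by default (opt-out
  flag), since the reasoning scheme assumes both directions exist.
* Negatives are resampled per batch per epoch (not fixed per epoch).
* Entities missing from the type table get type `UNKNOWN` with a warning;
  type-aware sampling refuses untyped tails rather than guessing.
* The symmetric score implements the averaged-logit rule literally, both
  terms conditioned on the source u. Exchanging endpoints changes the
  source, so exact u↔v symmetry is not guaranteed; the empirical gap is
  measured (mean ≈ 0.14 on a trained benchmark model) and reported rather
  than forced to zero.
* Batches are flat lists of positive triplets; each query in a batch is
  scored against all tails in one forward pass, and per-query scores are
  independent of batch composition by construction.
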