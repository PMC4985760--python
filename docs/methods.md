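# Methods

## Model and procedure

A dynamic network is a sequence of undirected weighted snapshot graphs
A_1, …, A_T on possibly changing node sets.  The goal at each snapshot
is a hard partition into k_t communities that fits the current graph
while staying temporally smooth.

**Similarity views.**  Node i is represented by its adjacency column
x_i^t (an n-vector of edge weights).  Per snapshot, one similarity
matrix per kernel is built on these features:

* linear: W_ij = ⟨x_i, x_j⟩ — for 0/1 adjacencies this counts common
  neighbors;
* Gaussian: W_ij = exp(−‖x_i − x_j‖² / 2σ²), σ = median of the
  n(n−1)/2 pairwise Euclidean column distances (recomputed per
  snapshot; floored at 10⁻¹² if all columns coincide).

Diagonals are zeroed (self-similarity contributes nothing to a cut;
configurable via `KernelSpec.zero_diagonal`).  Both kernels are exact
symmetrizations, so similarity matrices satisfy W == Wᵀ bit-for-bit.

**Spectral core.**  For a similarity W the symmetric normalized
Laplacian is L = I − D^{−1/2} W D^{−1/2} with ε_d = 10⁻¹⁰ added to all
degrees before the inverse square root, so isolated nodes (common in
short-interval snapshots) stay finite.  The relaxed normalized-cut
embedding is the eigenvector block of the k smallest eigenvalues;
rows are normalized to unit length before k-means (the embedding's
radial component carries no cluster information and degrades centroid
geometry otherwise).  k-means uses greedy k-means++ seeding with 10
restarts and a threaded seed; every runner derives the snapshot-t seed
as `seed + t`, which makes whole pipelines bit-reproducible and lets
reduction identities (e.g. PCQ at α=1 equals the static baseline) hold
as exact label equality.

**Co-training with temporal smoothing.**  Per snapshot, each view q
yields an embedding U_q^t.  The temporal projector of view q is the
convex blend

    H_q = α_q U_q^t (U_q^t)ᵀ + (1 − α_q) U_q^{t−1} (U_q^{t−1})ᵀ,

a symmetric matrix with spectrum in [0, 1] and trace
α_q k_t + (1−α_q) k_{t−1} (community counts may change freely; the
projector blend is insensitive to it).  Each view's similarity is then
replaced by S̃_p = sym(H̄ S_p) with H̄ the mean of the *other* views'
projectors and sym(M) = (M+Mᵀ)/2 — the projection suppresses
components of S_p orthogonal to where the other views (and the recent
past) put the cluster structure.  The projected similarity can acquire
small negative entries and a nonzero diagonal; both are clipped to
zero before the next Laplacian, which preserves symmetry and the
validity of the normalized-cut relaxation.  After the configured
number of rounds the final embeddings are concatenated column-wise
(n × Σk) and clustered by k-means; alternatively a single "most
informative" view's embedding can be used (`combine="single_view"`).

**Adaptive temporal weight.**  Per view,

    α = max(α_floor, 1 − ‖W_t − W_{t−1}‖_F / max(‖W_t‖_F, ‖W_{t−1}‖_F)),

computed on the raw (pre-co-training) similarities after aligning the
node sets, with α = 1 at t = 1.  Properties: α = 1 for identical
views, monotone non-increasing in the drift, scale-invariant, and
never below the floor — the current snapshot always receives at least
as much weight as history.  The floor defaults to ½; per-view weights
can be averaged into a shared one (`share_alpha`).

**Node churn and changing k.**  The history carried between snapshots
(per-view embeddings and raw similarities, plus the node list) is
aligned to each new snapshot: rows (and columns) of departed nodes are
deleted, inserted nodes get zero rows/columns — a new node carries no
historical projection mass, so its assignment is driven purely by
current data.  The carried embeddings are the snapshot's final
post-co-training ones (they define the partition actually reported);
the carried similarities are pre-co-training, since the α estimator
measures raw data drift.

**Baselines.**  PCQ blends the current relaxed cost matrix with the
previous snapshot's (NC: normalized Laplacians; NA: similarity
matrices, maximizing); PCM blends the current cost matrix with the
previous relaxed membership projector U_{t−1}U_{t−1}ᵀ.  Both reduce
exactly to the static baseline at α = 1 and at t = 1, and PCM at α = 0
reproduces the previous projector exactly.  These are structural
reconstructions at the relaxed-eigenproblem level of the published
framework they follow, intended for comparison, not bit-exact ports.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `kernels` | gaussian + linear | similarity views (≥ 2) |
| `iterations` | 1 | co-training rounds; the first round gives most of the gain and the iteration does not converge in general |
| `alpha_mode` / `alpha_fixed` | adaptive | drift-based α vs a fixed value in [0,1] |
| `alpha_floor` | 0.5 | least weight ever given to the current snapshot |
| `combine` | concat | embedding combination for the final k-means |
| `n_clusters` | — | communities per snapshot (scalar or per-snapshot list); selecting k automatically is out of scope |
| baseline `alpha` | 0.9 | conventional comparison setting for PCQ/PCM |

## Synthetic benchmarks

The generators emit `DynamicNetwork`s with per-snapshot ground truth
and are deterministic functions of their seed.

* **Dynamic planted partition** (`gen_gn_dynamic`): n=128 nodes, k0=4
  communities of 32.  Given the mean inter-community degree z and the
  total expected degree d, edge probabilities are p_out = z/(n−n_c)
  and p_in = (d−z)/(n_c−1), so the expected degree is exactly d.  At
  each snapshot t ≥ 2, Cn members per community move to one of the
  other communities uniformly (a `churn_total` switch draws the
  movers network-wide instead); edges are redrawn independently every
  snapshot conditional on current memberships — membership dynamics
  are specified, edge persistence is not, so snapshots are
  conditionally independent.
* **Fixed / variable community counts** (`gen_syn_fix`, `gen_syn_var`):
  SYN-FIX is the 128-node benchmark with d=16 and 3 movers per
  community.  SYN-VAR starts from 256 nodes in 4 communities of 64; at
  each t in 2..5 a new 32-node community forms from 8 members of each
  original community and dissolves 5 timestamps later (its members
  return to their origins), giving the community-count trajectory
  4,5,6,7,8,8,7,6,5,4; additionally 16 nodes are deleted and 16
  inserted per snapshot.  Deletions skip nodes currently on an
  excursion (so every departed node can return); inserted nodes copy
  the community (and origin) of a uniformly drawn survivor.  With
  unequal community sizes, within-community probabilities are
  (d−z)/(|c|−1) and cross-community probabilities average the two
  endpoints' z/(n−|c|) rates, keeping each node's expected degree ≈ d.
* **Event benchmarks** (`gen_event_network`): 1000 nodes, 10
  snapshots, community sizes drawn in [20,100], target mean degree 15
  (within-community probability (1−μ)·15/(|c|−1), cross-community
  μ-controlled), a hard degree cap of 50 enforced by removing random
  incident edges, and 20% of memberships permuted per snapshot.
  Exactly one event of the requested type is embedded mid-sequence
  (birth at t=4 + death at t=7; expansion/contraction/switch at t=5;
  merge at t=4 + split at t=7), with donor/host communities chosen so
  all sizes stay within bounds.  This is a simplified
  configuration-model realization of the event-benchmark idea — degree
  targets hold in expectation rather than via a power-law machinery —
  so its absolute scores are not comparable to other implementations
  of the concept.

## Evaluation

NMI = I(p, g) / ((H(p)+H(g))/2), natural logarithms (the normalization
makes the value base-invariant); by convention 1 when both partitions
are single-cluster and 0 when exactly one is.  SSE =
‖ẐẐᵀ − GGᵀ‖_F² over one-hot indicator matrices, computed from the
contingency table as Σ|c_p|² + Σ|c_g|² − 2Σn²; it is
label-permutation-invariant, 0 iff the partitions agree up to
relabeling, and its random-partition expectation on the 128-node /
4-community design is ≈ 6.0×10³ (the "noise floor" a failed clustering
sits at, against which order-10² values indicate a handful of
misplaced nodes).  Partitions over different node sets are compared on
the intersection.  Experiment aggregation averages per-snapshot values
over snapshots and then over repeated runs, each run drawing fresh
generator and method seeds from one master seed sequence.

## Numerical choices and degenerate inputs

Eigendecompositions are dense symmetric solves restricted to the
needed index range; embedding projectors (not eigenvector signs) are
the well-defined object, and tests compare projectors wherever an
eigengap guarantees uniqueness.  Zero-degree nodes are regularized
(ε_d above); an edgeless graph clusters deterministically under a
fixed seed with a warning.  Ties in k-means are resolved by inertia
across the 10 restarts by the underlying solver.  Identical feature
columns floor σ at 10⁻¹² rather than dividing by zero.

## What the synthetic experiments do and do not show

The generators redraw edges independently per snapshot and plant
equal-probability blocks; real dynamic networks have persistent edges,
heavy-tailed degrees and overlapping communities, none of which is
emulated.  Passing benchmarks therefore demonstrates correctness of
the machinery and behavior under controlled drift, not performance on
real data.

Two observed regimes are worth stating plainly.  On clearly detectable
structure (e.g. z=4 of degree 20; signal eigenvalue of the expected
adjacency well above √d), all methods are at or near NMI 1 and the
multi-view method is never worse than the static baseline.  Deep in
the noisy regime (z ≳ 8 of degree 16, near the spectral detectability
threshold) the adjacency-column kernels are a *weaker* representation
than the raw adjacency — quadratic common-neighbor statistics lose
signal in sparse noise — and the co-trained method inherits that
deficit from its views; co-training and temporal smoothing each add a
small gain on top of the views but do not recover the gap.  Users
working near the detectability threshold should prefer the raw
adjacency as one of the views or the static/PCM baselines.

## Known limitations

* k must be supplied per snapshot; no automatic model selection.
* Hard partitions only; no overlapping or soft memberships.
* Full per-snapshot eigendecompositions (O(n³)); no landmark or
  Nyström acceleration, so n in the tens of thousands is out of reach.
* The event generator realizes the benchmark concept in simplified
  form (see above).
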