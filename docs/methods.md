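# Methods

## Problem and model

`jointmds` aligns two or three datasets that describe the same samples in
unrelated feature spaces (for instance bulk RNA-seq, DNA methylation and MRI
radiomics of the same patients) into one low-dimensional space, without using
the known correspondences. Each domain enters only through its within-domain
dissimilarity matrix, so the feature spaces never need to be comparable.

For two domains with dissimilarities D ∈ R^{n×n}, D′ ∈ R^{n′×n′} the method
minimizes

    stress(Z, D, W) + stress(Z′, D′, W′) + 2λ ⟨P, d²(ZO, Z′)⟩_F

over embeddings Z ∈ R^{n×d}, Z′ ∈ R^{n′×d}, an orthogonal transform
O ∈ O_d and an entropically regularized transport plan P ∈ Π(a, b).
`stress` is weighted raw MDS stress summed over ordered pairs i ≠ j with
symmetric weights (default W = 1/n² off-diagonal); d²(ZO, Z′) is the matrix
of squared distances between the rotated first embedding and the second.
λ ≥ 0 trades within-domain geometry preservation against cross-domain
matching; the plan's entropy weight ε > 0 controls how soft the
correspondences are.

The optimization alternates two blocks:

1. **Wasserstein–Procrustes** with the embeddings fixed: Sinkhorn scaling in
   the log domain solves the entropic transport problem for P, and the SVD of
   ZᵀPZ′ gives the optimal O (reflections permitted — the constraint set is
   the full orthogonal group). Each alternation performs
   Sinkhorn → Procrustes → Sinkhorn, so the returned P is consistent with the
   returned O.
2. **Stacked SMACOF** with (P, O) fixed: the coupling term is treated as
   stress toward target dissimilarity 0 with weight λP_ij per ordered cross
   pair, which makes the whole objective a single weighted-MDS problem on the
   stacked (n+n′)-point configuration [Z·O ; Z′] with block dissimilarities
   [[D, 0], [0, D′]] and block weights [[W, λP], [λPᵀ, W′]]. One Guttman
   transform on this system never increases the joint objective.

The outer loop stops when the relative Frobenius change of P drops below
`tol_P` (default 1e−5) or after `max_outer` (default 100) iterations;
non-convergence is reported as a flag, not an error.

### What the monotone trace measures

The alternation provably decreases the *entropy-regularized* objective
stress + stress′ + 2λ(⟨P, C⟩ − εH(P)), because the Sinkhorn block optimizes
the entropic transport problem, not ⟨P, C⟩ alone. `JointMDSResult.trace`
stores this regularized objective per outer iteration (non-increasing once ε
has reached its target value) and `JointMDSResult.objective` stores the
plain unregularized value for reporting.

## Initialization and registration robustness

Embedding-level alternation refines whatever registration it starts from:
with a cold start (O = I, product coupling), planted-rotation experiments
show it locks into rigid-motion local optima (a 30° rotation is already
unrecoverable). The package therefore decides the registration *before*
embeddings exist:

- **Gromov–Wasserstein coupling initialization** (default,
  `coupling_init="gw"`): an entropic square-loss GW match between the two
  input dissimilarity matrices (projected mirror descent — each step
  linearizes the GW objective and calls Sinkhorn) seeds P; the Procrustes
  transform of that coupling seeds O, followed by a few coupled majorization
  steps. Registration is thus derived from global distance structure, which
  removed essentially all seed-to-seed registration failures in our
  benchmarks.
- `coupling_init="uniform"` reproduces the plain alternation, helped by two
  devices: ε-annealing (the transport regularization starts at the cost scale
  and decays by `eps_decay` per outer iteration toward the target, letting
  the coupling sharpen as the embeddings co-adapt) and nearest-neighbour-cost
  screening of orthogonal starting candidates (a deterministic
  rotation/reflection grid in d = 2, Haar samples otherwise).
- `n_starts > 1` runs the whole procedure from several random
  initializations and returns the run with the lowest final objective. On
  data with near-symmetric geometry (rings, balanced forks) misregistered
  optima can score as well as the truth — an identifiability limit of
  unsupervised alignment that no start-selection rule can cross.

## Sinkhorn numerics

Log-domain scaling with ε-annealed cold starts and warm-started dual
potentials across outer iterations (potentials are discarded when O jumps
far, where a fresh annealed start converges faster). In the small-ε regime
the marginal residual of raw Sinkhorn decays only like O(1/iterations), so
the alignment loops run with `round_marginals=True`: after the iteration
budget the plan is projected onto Π(a, b) exactly (row/column rescaling plus
a nonnegative rank-one correction — the classic feasibility rounding). The
standalone `sinkhorn()` keeps strict semantics by default and raises
`SinkhornError` with the residual when the tolerance is not met. Entropy
uses the convention H(P) = −Σ P(log P − 1), under which the scaling fixed
point is the exact optimum of the regularized problem.

## Three-domain extension

With core A and satellites B, C (`joint_mds3`):

1. joint MDS(A, B) and joint MDS(A, C). Both runs share the core's random
   starting configuration so A's two embeddings differ only through their
   partners.
2. The two core embeddings A_B and A_C are matched by a joint MDS run on
   their (unnormalized) Euclidean distance matrices, initialized from the
   embeddings themselves and with the embeddings *frozen* (`n_inner=0`):
   only the coupling and the orthogonal map O between the two frames are
   optimized, since those are the only step outputs consumed downstream.
   Freezing keeps the merged core exactly continuous with the satellites'
   frames; letting the merge deform the core (we tested both) introduces
   drift that the rigid satellite carry-over cannot follow.
3. The A_C-side frame is the common frame: B_AC = B_A·O, C_AB = C_A, and the
   merged core is the A_C-side embedding. The step-2 coupling is kept for
   diagnostics only — rows are never permuted, preserving the 1–1 sample
   identity that FOSCTTM requires.

All post-alignment maps are isometries, so within-domain distance matrices
of the final embeddings equal those of the pairwise runs exactly. The
three domains must have equal sample counts (pairwise alignment itself
permits n ≠ n′).

## Dissimilarities

Euclidean distances, or geodesic distances on a k-nearest-neighbour graph
(union symmetrization — an edge is kept if either endpoint selects it; ties
broken toward the smaller sample index; all-pairs shortest paths by
Dijkstra). Disconnected graph components are bridged through their closest
point pair at Euclidean weight, with a warning, so no sample is dropped.
Zero-length edges between coincident points receive a negligible positive
weight (1e−300) because sparse arithmetic would silently drop stored zeros.
Before alignment each matrix is divided by its maximum entry by default,
since the joint objective mixes stress across modalities of incomparable
scale.

## Synthetic benchmark generator

`make_triplet` emulates the standard labelled manifold-alignment testbed:
300 samples from one of three manifolds, rendered as three heterogeneous
domains (1000 and 2000 dimensions by Gaussian random projection with
i.i.d. N(0, 1/q) entries; a 500-dimensional third domain built by applying
the principal axes of the column-concatenated pair to the first domain),
each with additive i.i.d. N(0, 0.05²) noise. Manifold coordinates are
standardized to zero mean and unit RMS before projection so the three kinds
enter the noise model on one footing.

- *bifurcation*: a 2-D trajectory splitting at its midpoint into two noisy
  branches with different angles and lengths. The asymmetry is deliberate:
  mirror-symmetric branches would make branch identity unrecoverable from
  within-domain distances by any method.
- *swiss_roll*: the classic 3-D roll (t·cos t, h, t·sin t), labelled by
  three contiguous bands of the roll parameter.
- *circular_frustum*: points on a truncated-cone surface, labelled by three
  angular sectors.

With n = 300 samples the combined 300×3000 matrix has at most 299 principal
axes, so a 500-dimensional third domain cannot come from principal axes
alone: the remaining columns use a seeded orthonormal complement and carry
noise only. Generators are pure functions of (parameters, seed).

What the generator does *not* emulate: dropout/zero inflation, batch
effects, heavy-tailed count noise, unequal sample availability between
modalities. Passing the triplet benchmark therefore demonstrates correct
geometry recovery under clean projective corruption, not robustness to
real multi-omics artefacts.

## Evaluation

FOSCTTM uses strict inequality ("closer" ties do not count against the true
match), is computed in both directions and averaged over all samples; it is
invariant under any common rigid motion. Label transfer fits a k-NN
classifier (k = 5, Euclidean, majority vote) on one domain's final embedding
and scores it on the other; distance ties resolve toward the smaller
training index and vote ties toward the lexicographically first label.
Three-domain runs are scored on the three final embedding pairs
(1–2, 1–3, 2–3) and averaged. `repeated_runs` aggregates any per-seed metric
over seeds base..base+n−1 with mean and population standard deviation.

## Feature selection

Zero-variance features are dropped first. With a binary diagnosis the
two-sided Mann–Whitney U test (midranks; exact enumeration of all group
assignments when both groups have ≤ 8 samples, tie-corrected normal
approximation otherwise) is Bonferroni-corrected across all tested features
(p_corr = min(1, m·p)); features with p_corr < α survive, optionally
truncated to the top-N smallest corrected p-values (customary N per
sequencing modality: 5000 RNA-seq, 10000 methylation, 4000 CNV). Without
labels, features are kept when unbiased variance divided by mean exceeds
0.01; non-positive means make the ratio undefined and such features are
dropped with a warning (radiomic features can be negative). Exact two-sided
p-values use 2·min(P(U ≤ u), P(U ≥ u)) capped at 1.

## Defaults and problem sizes

| parameter | default | role |
| --- | --- | --- |
| d | 2 | embedding dimension (the standard visual/benchmark setting) |
| λ | 1 | matching penalty; with uniform W the within-stress mass is 1 per domain and the cross term 2λ |
| ε | 0.01 (alignment API), 0.001 in the benchmark scripts | entropy of the coupling; dissimilarities are max-normalized so ε is on a [0,1]² cost scale |
| k | 10 | kNN graph size for geodesics; grid-searched per pair in the benchmarks |
| tol_P | 1e−5 | relative Frobenius change of P stopping the outer loop |
| max_outer | 100 | outer iteration cap |
| n_inner | 5 | SMACOF steps per outer iteration |
| SMACOF tol | 1e−6 | relative stress change, max 300 iterations |

The acceptance script and the headline test regenerate each synthetic kind
at full size (n = 300, domains of 1000/2000/500 dimensions), select
(k, ε, λ) from the grid {5, 10} × {0.001} × {1, 10} by the triplet's
average FOSCTTM (the reported quantity; a single-pair proxy tracks it only
loosely), and average five seeds per kind — small enough to run on one CPU
in a few minutes per kind while exercising the complete pipeline.

## Known limitations

- Unsupervised alignment cannot resolve true symmetries of the data: on
  manifolds with exact rotational or mirror symmetry the correct
  registration is not identifiable from dissimilarities, and near-symmetry
  leaves misregistered optima whose objective is competitive.
- The GW initializer and the alternation are both non-convex; results are
  deterministic per seed but only locally optimal.
- The three-domain carry-over is rigid, so residual non-rigid discrepancy
  between the core's two pairwise embeddings propagates to the satellites.
- Geodesic distances inherit kNN-graph artefacts (short-circuits at large k,
  fragmentation at small k); k matters and should be grid-searched.
- All-pairs shortest paths and dense Guttman solves scale quadratically to
  cubically in sample count; the intended regime is cohorts of order 10²–10³
  samples.
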