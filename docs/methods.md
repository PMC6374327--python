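# Methods

## Problem and data model

The package classifies subjects from voxel-wise *binary* cortical
morphology: each subject contributes a 0/1 volume on a shared grid in a
standard space, where 1 marks cortical gray matter (extracted from a
FreeSurfer-style parcellation by binarizing an inclusive label range,
251–2035 by default).  Unlike gray-matter-concentration maps, these
volumes carry shape only — the feature for voxel *v* is simply whether
subject *s* has cortex at *v*.  Columns that are all-0 or all-1 across
subjects carry no between-subject information and are removed before any
modeling; all provenance is kept as linear voxel indices in a fixed
Fortran flattening order (first axis fastest, 0-based, NIfTI affine
convention).

## The feature-selection cascade

Voxel counts at full resolution are orders of magnitude larger than cohort
sizes, so feature selection is done coarse-to-fine on a factor-2 resolution
pyramid (e.g. 0.7 mm → 1.4 mm → 2.8 mm):

1. **Downsampling.** Binary volumes are aggregated over 2×2×2 blocks.
   The aggregation rule is block majority with ties rounding to 1
   (options: `any`, `all`); majority preserves the thin cortical ribbon
   better than `all` and inflates it less than `any`.  Edge blocks on odd
   shapes use their actual size.  The affine is rescaled so output voxels
   sit at their source-block centers.
2. **Per-fold ranking.** Within each cross-validation fold, candidate
   voxels are ranked on the training rows only by the l2,1-norm robust
   feature selector (below).
3. **Feature-count grid search.** For each count k in a grid
   (step, 2·step, …, k_max; 200/10,000 by default, truncated and capped at
   the candidate count d), a linear SVM is trained on each fold's top-k
   voxels and scored on that fold's test rows; the overall accuracy for k
   is the fold mean.  best_k is the smallest k attaining the maximum —
   the parsimonious, deterministic tie rule.
4. **Union and expansion.** The union over folds of each fold's top-best_k
   voxels is the level's selection; its voxels are expanded to their (up
   to 8) children on the next finer grid, children removed as constant
   columns are dropped, and steps 2–4 repeat.  A single level run on all
   of its features is the "direct sparsity" baseline; PCA + SVM (components
   fitted on training rows only) is the second baseline.

The same fold plan is reused at every level (re-drawing per level is a
config option); reusing it prevents subjects from drifting between
training and test roles across levels.  Because best_k is chosen on the
same folds that report accuracy, the protocol's accuracy estimate carries
a modest optimistic bias; this mirrors the printed protocol as literally
as possible and is documented rather than patched with an inner split.

## The l2,1 feature selector

Features are ranked by solving

    min_W  J(W) = ||A W − Y||_{2,1} + γ ||W||_{2,1}

with A the n×(d+1) training matrix (bias column appended and excluded from
ranking), Y the n×2 one-vs-rest indicator, and ||M||_{2,1} the sum of row
Euclidean norms.  The l2,1 loss caps each subject's influence (robustness
to outlying masks); the l2,1 penalty zeroes whole rows, and features are
ranked by ||w^i||₂ (ties broken by ascending index).  γ defaults to 0.01,
the standard default for this estimator; it is exposed in the config.

The solver is iteratively reweighted least squares: with residual-row
norms r and weight-row norms q, the next iterate solves the weighted ridge
normal equations, evaluated in the n×n dual form
W = Q Aᵀ (A Q Aᵀ + γ R)⁻¹ Y (Q = diag q, R = diag r), costing O(n²d) per
iteration independent of d².  Row norms are smoothed as √(r² + ε²) with
ε = 10⁻⁸ × the initial objective; because √· is concave, each iteration is
a majorize–minimize step on the ε-smoothed objective, so the objective
trace is guaranteed non-increasing (asserted in tests, and checked against
a generic convex minimizer on small instances).  Initialization is ridge
regression with λ = γ; convergence is a relative objective change below
10⁻⁶ or 200 iterations.  A singular system falls back to a small ridge
addition and flags the solution.

## Classification and inference

The classifier is a soft-margin linear SVM, C = 1, labels −1/+1,
decision threshold 0 (sign(0) counts as +1).  Folds are stratified by
default (class proportions per fold within one subject), deterministic
given a seed.  Performance is accuracy at threshold 0 and the AUC of the
continuous decision scores.

*Permutation test.*  Features and folds held fixed, the full label vector
is permuted uniformly per replicate and the cross-validated evaluation is
rerun, pooling test scores into one AUC per replicate (a per-fold variant
is available).  The p-value uses the add-one rule
(1 + #{null ≥ observed}) / (1 + n_perm), so its minimum with 1,000
replicates is 1/1001 — consistent with reporting p < 0.001.

*Weight maps.*  A trained SVM's voxel weights are
g = |Σᵢ αᵢ yᵢ xᵢ| = |h| element-wise (the dual/primal identity is asserted
to 10⁻⁶).  The bootstrap map retrains on 90% subsamples drawn without
replacement (the literal reading of "90% randomly chosen"; replicates are
redrawn if a class is lost) and averages g.  Maps can be max-1 normalized
and written back to the grid as NIfTI.

*Cluster report.*  Voxels above a weight quantile (default 0.999, computed
with the conservative "higher" method so the table empties as the quantile
approaches 1) are grouped by 26-connectivity; clusters under `min_size`
(default 100 voxels, the scale of reportable clusters) are dropped;
centroids are reported in world mm via the affine, hemisphere from the
centroid's world-x sign (x < 0 → L, midline → R).

*Atlas analysis.*  Each region of an anatomical or network label volume is
classified from all of its surviving voxels directly (no feature
selection; an optional flag enables per-region ranking); empty regions get
null metrics, and mask voxels outside every region are counted as an
"unassigned" pseudo-region.

## Synthetic cohorts

The generator emulates the features of a real cohort that the pipeline is
sensitive to, on grids small enough for desk-scale runs:

- a **cortical-shell template**: an ellipsoidal shell (semi-axes 0.42× the
  grid shape, thickness half the smallest semi-axis) standing in for the
  cortical ribbon — most of its interior is constant across subjects and
  is removed by the constant-column filter, exactly as common cortex is in
  real masks;
- **boundary jitter**: voxels within one voxel of the template boundary
  flip independently with probability 0.05 per subject, emulating
  inter-subject ribbon variability; interior voxels are untouched so
  implanted effects are never diluted;
- **discriminative clusters**: spherical clusters (default two, radius 3
  voxels ≈ 120 shell voxels each — the scale of reportable clusters)
  whose voxels are occupied with probability p₊ = 0.9 in group +1 and
  p₊ − effect_size in group −1, assigned after jitter so truth voxels
  carry exactly the designed marginal effect.  By default cluster voxels
  are drawn independently; `cluster_coherence` ∈ [0, 1] optionally makes
  that fraction of each cluster copy one per-subject latent Bernoulli
  draw, emulating a regionally coherent morphological difference without
  changing any marginal occupancy.

The cohort is a pure function of its spec (one seeded RNG stream, fixed
subject order).  Default cohort size is 100 subjects per group.  What the
generator does **not** emulate: real neuroanatomy (gyri, hemispheres,
atlas geometry), spatially correlated boundary noise, registration error,
or site effects — so green tests demonstrate the pipeline's mechanics and
statistical calibration, not performance on real cortical data.

Cluster radius interacts with the pyramid: a cluster is visible at a
coarser level only where it dominates the majority vote of a block, so
radius-3 clusters are near the smallest that survive two factor-2
downsamplings; smaller implants vanish from the coarsest level and cannot
seed the cascade.

## Known limitations

- **Selection vs. localization.**  The l2,1 ranking is a sparse-regression
  ranking: when many truth voxels carry redundant signal it concentrates
  weight on a subset sufficient for regression rather than on all of them,
  and in the d ≫ n regime roughly n of the top rows serve interpolation
  rather than association.  Consequently the union-of-top-best_k selection
  is strongly *enriched* for true effect voxels (several-fold over base
  rate, asserted in tests) but is not a consistent estimator of the full
  effect support: on strong-effect synthetic cohorts its voxel-level
  precision and recall plateau near 0.5 even when classification accuracy
  is 1.0.  The best_k tie rule compounds this: once accuracy saturates,
  the smallest maximizing k is selected, bounding the selection size well
  below large implanted supports.  Bootstrap weight maps are the better
  localization tool and do separate truth from noise voxels cleanly.
- The grid-search step should scale with the candidate count; at
  desk-scale feature counts the full-scale 200-interval step skips the
  informative range, so scaled runs use a proportionally smaller step.
- Accuracy reported by the grid search is mildly optimistic (best_k chosen
  on the same folds); an unbiased estimate would need an outer loop.
- Binary features make per-voxel test statistics non-Gaussian; all
  inference here is permutation/bootstrap-based for that reason.
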