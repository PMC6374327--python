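# hsrc — hierarchical sparse feature selection for binary cortical morphology

`hsrc` classifies subjects (e.g. by sex) from voxel-wise **binary cortical
morphology**: per-subject 0/1 volumes on a common grid where 1 marks
cortical gray matter, typically obtained by binarizing a FreeSurfer-style
parcellation (labels 251–2035).  It is aimed at neuroimaging researchers
doing multivariate pattern analysis on shape rather than gray-matter
concentration, and at methodologists who want a fully synthetic, seeded
test bed for sparse voxel selection.

At its core is a coarse-to-fine feature-selection cascade over a factor-2
resolution pyramid.  At each resolution, every cross-validation fold ranks
candidate voxels with the **l2,1-norm robust feature selector**

    min_W  ‖XᵀW − Y‖₂,₁ + γ‖W‖₂,₁ ,   ‖M‖₂,₁ = Σᵢ ‖mᵢ‖₂ ,

solved by iteratively reweighted least squares (monotone objective,
O(n²d) per iteration), where the columns of X ∈ ℝ^{d×n} are the fold's
training subjects (a bias column is absorbed into W) and Y ∈ {0,1}^{n×2}
is the one-vs-rest label indicator.  A linear soft-margin SVM (C = 1) is
trained on each fold's top-k voxels over a grid of counts k; the smallest
k with the best fold-averaged accuracy wins, the union over folds of each
fold's top-best_k voxels becomes the level's selection, and those voxels'
2×2×2 children seed the next finer level.  Inference tooling includes a
label-permutation null for the cross-validated AUC, bootstrap voxel-weight
maps g = |Σᵢ αᵢyᵢxᵢ| = |h|, a 26-connectivity cluster report in world-mm
coordinates, and atlas-based per-region classification.  A seeded
synthetic-cohort generator (ellipsoidal cortical shell, boundary jitter,
implanted effect clusters) makes every stage testable without any imaging
data.

## Worked example

Simulate a 60-subject cohort (two groups of 30 on a 16³ grid, two
implanted clusters with an occupancy effect of 0.6), run a two-level
cascade, and test significance:

```sh
hsrc simulate --out demo/cohort --n-per-group 30 --shape 16 \
     --cluster-radius 2.0 --seed 5
# wrote 60 subjects, 64 ground-truth voxels -> demo/cohort

hsrc run-hsrc --cohort demo/cohort --out demo/run \
     --levels 2 --k-max 100 --step 20 --folds 5
# {"best_k": 20, "mean_accuracy": 1.0, "mean_auc": 1.0, "n_selected": 60}

hsrc permute --cohort demo/cohort --out demo/perm --n-perm 100 --perm-seed 3
# {"observed_auc": 1.0, "null_mean_auc": 0.4681, "p_value": 0.009900990099009901, "n_perm": 100}
```

Reading the output: at the finest level the grid search kept `best_k = 20`
voxels per fold (their union, `n_selected = 60`, is written as a NIfTI
mask per level), and 5-fold cross-validation classifies every held-out
subject correctly (`mean_accuracy = 1.0`) — expected, since the implanted
effect is strong.  The permutation run shows the null AUC centered near
0.5 (`null_mean_auc = 0.4681`) with the observed AUC of 1.0 beating all
100 permutations, giving the add-one p-value 1/101 ≈ 0.0099.  `demo/run/`
also contains `accuracy_vs_k.csv` (the accuracy-versus-feature-count
curves per level) and a `config.json` echo of every resolved setting for
exact reruns.

The same pipeline is available as a library:

```python
from hsrc import (SyntheticSpec, generate_cohort, assemble_feature_matrix,
                  downsample_binary, build_pyramid, make_folds, run_cascade)

cohort = generate_cohort(SyntheticSpec(seed=1))
fine = cohort.volumes
mid = [downsample_binary(v, 2) for v in fine]
coarse = [downsample_binary(v, 2) for v in mid]
mats = [assemble_feature_matrix(v, cohort.subject_ids) for v in (fine, mid, coarse)]
pyramid = build_pyramid(fine[0].grid, 3)
folds = make_folds(len(fine), 10, cohort.labels, seed=1)
result = run_cascade(mats, cohort.labels, folds, pyramid, step=25)
print(result.final_mean_accuracy)
```

See `docs/methods.md` for the model, the solver, the synthetic-data design
and known limitations (in particular: the sparse ranking *enriches* for
true effect voxels but is not a consistent estimator of the full effect
support; use the bootstrap weight map for localization).

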