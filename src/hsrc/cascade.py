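"""Hierarchical coarse-to-fine sparse feature selection and classification.

At each resolution level, every cross-validation fold ranks the candidate
voxels with the l2,1 robust feature selector on its training rows only; a
grid of feature counts k is evaluated by training a linear SVM on each
fold's top-k features and averaging the fold test accuracies.  The smallest
k attaining the best average accuracy wins, and the union over folds of the
top-best_k features becomes the level's selection.  Selected voxels are
expanded to their (up to 8) children at the next finer resolution and the
procedure repeats; running a single level on all of its features is the
"direct sparsity" baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classify import ClassifierModel, EvalResult, FoldPlan, evaluate, train_svm
from .rfs import DEFAULT_GAMMA, make_label_matrix, rank_features, solve_rfs
from .volumes import FeatureMatrix, ResolutionPyramid

__all__ = [
    "GridSearchResult",
    "CascadeResult",
    "make_k_grid",
    "grid_search_level",
    "direct_sparsity",
    "expand_selection",
    "run_cascade",
]

logger = logging.getLogger(__name__)

DEFAULT_K_MAX = 10_000
DEFAULT_K_STEP = 200


@dataclass
class GridSearchResult:
    """Feature-count grid search at one resolution level.

    ``selected_union`` and ``per_fold_selected`` hold column indices into
    the level's FeatureMatrix; ``selected_voxels`` the corresponding voxel
    linear indices.  ``models`` are the per-fold SVMs trained at ``best_k``
    (training rows only — used for weight maps and leakage audits).
    """

    k_grid: np.ndarray
    fold_accuracy: np.ndarray  # (n_folds, n_k)
    overall_accuracy: np.ndarray
    best_k: int
    selected_union: np.ndarray
    per_fold_selected: list[np.ndarray]
    selected_voxels: np.ndarray
    fold_eval: list[EvalResult] = field(default_factory=list)
    models: list[ClassifierModel] = field(default_factory=list)
    fold_rankings: list[np.ndarray] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        """Overall accuracy at best_k (mean of fold test accuracies)."""
        return float(self.overall_accuracy[int(np.argmax(self.overall_accuracy))])

    @property
    def mean_auc(self) -> float:
        return float(np.mean([r.auc for r in self.fold_eval]))


@dataclass
class CascadeResult:
    """Cascade output: one grid search per level, coarsest first."""

    per_level: list[GridSearchResult]
    final_voxels: np.ndarray
    final_eval: list[EvalResult]

    @property
    def final_mean_accuracy(self) -> float:
        return self.per_level[-1].mean_accuracy

    @property
    def final_mean_auc(self) -> float:
        return self.per_level[-1].mean_auc


def make_k_grid(k_max: int, step: int, d: int | None = None) -> np.ndarray:
    """Feature-count grid [step, 2*step, ..., k_max], capped at d.

    With the default 10,000/200 settings this yields 50 candidate counts.
    When ``d`` (the available feature count) is below ``k_max`` the grid is
    truncated at d and d itself appended, so every count is usable.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if k_max < step:
        raise ValueError("k_max must be >= step")
    grid = list(range(step, k_max + 1, step))
    if d is not None:
        if d < 1:
            raise ValueError("d must be >= 1")
        grid = [k for k in grid if k < d]
        if (not grid or grid[-1] < d) and d <= k_max:
            grid.append(d)
        elif d > k_max:
            grid = list(range(step, k_max + 1, step))
    return np.asarray(grid, dtype=int)


def grid_search_level(
    F: FeatureMatrix,
    y: np.ndarray,
    folds: FoldPlan,
    k_grid: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    C: float = 1.0,
) -> GridSearchResult:
    """Per-fold RFS ranking + SVM accuracy over a grid of feature counts.

    For every fold, the l2,1 feature selector is fitted on the fold's
    training rows only and its ranking fixed; each k in ``k_grid`` then
    trains an SVM on the top-k columns and scores the fold's test rows.
    ``best_k`` is the smallest k attaining the highest fold-averaged
    accuracy; the level's selection is the union over folds of each fold's
    top-best_k columns.
    """
    y = np.asarray(y)
    k_grid = np.asarray(k_grid, dtype=int)
    if k_grid.size == 0:
        raise ValueError("k_grid must be non-empty")
    d = F.n_features
    if k_grid.max() > d:  # cap rule: truncate at d, then include d itself
        k_grid = np.unique(np.minimum(k_grid, d))
    X = F.X.astype(float)
    n_folds = folds.k
    fold_accuracy = np.zeros((n_folds, k_grid.size))
    rankings: list[np.ndarray] = []
    for f, (train, test) in enumerate(folds.split()):
        try:
            sol = solve_rfs(X[train], make_label_matrix(y[train]), gamma=gamma)
        except Exception as exc:  # noqa: BLE001 - annotate fold then re-raise
            raise RuntimeError(f"RFS failed in fold {f}: {exc}") from exc
        rankings.append(sol.ranking)
        for j, k in enumerate(k_grid):
            cols = sol.ranking[:k]
            model = train_svm(X[np.ix_(train, cols)], y[train], C=C)
            fold_accuracy[f, j] = evaluate(model, X[np.ix_(test, cols)], y[test]).accuracy
    overall = fold_accuracy.mean(axis=0)
    best_j = int(np.argmax(overall))  # argmax returns the first (smallest k) maximum
    best_k = int(k_grid[best_j])
    per_fold_selected = [r[:best_k].copy() for r in rankings]
    union = np.unique(np.concatenate(per_fold_selected))
    # refit per-fold models at best_k for evaluation artifacts
    fold_eval: list[EvalResult] = []
    models: list[ClassifierModel] = []
    for f, (train, test) in enumerate(folds.split()):
        cols = per_fold_selected[f]
        model = train_svm(X[np.ix_(train, cols)], y[train], C=C)
        models.append(model)
        fold_eval.append(evaluate(model, X[np.ix_(test, cols)], y[test]))
    return GridSearchResult(
        k_grid=k_grid,
        fold_accuracy=fold_accuracy,
        overall_accuracy=overall,
        best_k=best_k,
        selected_union=union,
        per_fold_selected=per_fold_selected,
        selected_voxels=F.voxel_index[union],
        fold_eval=fold_eval,
        models=models,
        fold_rankings=rankings,
    )


def direct_sparsity(
    F: FeatureMatrix,
    y: np.ndarray,
    folds: FoldPlan,
    k_grid: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    C: float = 1.0,
) -> GridSearchResult:
    """Single-resolution baseline: the grid search on one level's full features."""
    return grid_search_level(F, y, folds, k_grid, gamma=gamma, C=C)


def expand_selection(
    selected_voxels,
    pyramid: ResolutionPyramid,
    fine_F: FeatureMatrix,
) -> np.ndarray:
    """Children (next finer level) of selected coarse voxels, as fine voxel ids.

    The coarse and fine levels are located in the pyramid by grid shape;
    children that were removed as constant columns at the fine level are
    dropped.  The result is sorted (deterministic order).
    """
    fine_level = next(
        (i for i, g in enumerate(pyramid.levels) if g.shape == fine_F.grid.shape),
        None,
    )
    if fine_level is None or fine_level + 1 >= pyramid.n_levels:
        raise IndexError("fine feature matrix grid not found below a coarser level")
    selected_voxels = np.asarray(selected_voxels, dtype=np.int64)
    coarse_n = pyramid.levels[fine_level + 1].n_voxels
    if selected_voxels.size and (
        selected_voxels.min() < 0 or selected_voxels.max() >= coarse_n
    ):
        raise IndexError("selected coarse voxel index out of range")
    children = pyramid.children_of_many(fine_level, selected_voxels)
    present = children[np.isin(children, fine_F.voxel_index)]
    return present


def run_cascade(
    level_matrices: list[FeatureMatrix],
    y: np.ndarray,
    folds: FoldPlan,
    pyramid: ResolutionPyramid,
    k_max: int = DEFAULT_K_MAX,
    step: int = DEFAULT_K_STEP,
    gamma: float = DEFAULT_GAMMA,
    C: float = 1.0,
) -> CascadeResult:
    """Run the full coarse-to-fine cascade.

    ``level_matrices`` is ordered finest first, matching
    ``pyramid.levels``; the cascade starts at the last (coarsest) entry on
    all of its features and walks toward index 0, restricting each finer
    level's candidates to the children of the previous level's selection.
    The same fold plan is reused at every level.
    """
    if not level_matrices:
        raise ValueError("need at least one level")
    per_level: list[GridSearchResult] = []
    n_levels = len(level_matrices)
    for level in range(n_levels - 1, -1, -1):
        F = level_matrices[level]
        if level < n_levels - 1:
            prev = per_level[-1]
            child_voxels = expand_selection(prev.selected_voxels, pyramid, F)
            if child_voxels.size == 0:
                raise RuntimeError(
                    f"cascade level {level}: empty candidate set after expansion"
                )
            if child_voxels.size > 8 * prev.selected_voxels.size:
                raise AssertionError("expansion exceeded the 8-children bound")
            n_dropped = 8 * prev.selected_voxels.size - child_voxels.size
            logger.info(
                "level %d: %d candidate children (%d constant/truncated dropped)",
                level,
                child_voxels.size,
                n_dropped,
            )
            F = F.restrict(child_voxels)
        k_grid = make_k_grid(k_max, step, F.n_features)
        result = grid_search_level(F, y, folds, k_grid, gamma=gamma, C=C)
        logger.info(
            "level %d: d=%d best_k=%d acc=%.3f |union|=%d",
            level,
            F.n_features,
            result.best_k,
            result.mean_accuracy,
            result.selected_union.size,
        )
        per_level.append(result)
    final = per_level[-1]
    return CascadeResult(
        per_level=per_level,
        final_voxels=final.selected_voxels,
        final_eval=final.fold_eval,
    )
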