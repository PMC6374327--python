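"""Permutation significance testing, bootstrap weight maps, cluster report.

Statistical inference around the classifier: a label-permutation null
distribution for the cross-validated AUC, a per-voxel discriminability map
from the absolute SVM primal normal g = |sum_i alpha_i y_i x_i| averaged
over subsampled retrainings, and a connected-component report of the
high-weight voxels in world (MNI-mm) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .classify import ClassifierModel, FoldPlan, cross_validate_svm, train_svm
from .volumes import FLATTEN_ORDER, BinaryVolume, FeatureMatrix, voxel_to_mni

__all__ = [
    "PermutationResult",
    "WeightMap",
    "permutation_test",
    "svm_weight_vector",
    "bootstrap_weight_map",
    "cluster_report",
    "weight_map_to_volume",
]


@dataclass
class PermutationResult:
    """Null AUC distribution under label permutation, with add-one p-value."""

    null_auc: np.ndarray
    observed_auc: float
    n_perm: int

    @property
    def p_value(self) -> float:
        # add-one rule: p is never 0; minimum 1/(n_perm + 1)
        return float(
            (1 + np.sum(self.null_auc >= self.observed_auc)) / (1 + self.n_perm)
        )


@dataclass
class WeightMap:
    """Per-feature mean absolute SVM normal over bootstrap replicates."""

    g_bar: np.ndarray
    n_boot: int
    normalized: bool = False

    def normalize(self) -> "WeightMap":
        """Scale so the maximum weight is 1 (no-op on an all-zero map)."""
        m = self.g_bar.max()
        g = self.g_bar / m if m > 0 else self.g_bar.copy()
        return WeightMap(g_bar=g, n_boot=self.n_boot, normalized=True)


def _default_pipeline(X: np.ndarray, y: np.ndarray, folds: FoldPlan, C: float) -> float:
    """Pooled cross-validated AUC of a linear SVM (the default evaluation)."""
    _, pooled = cross_validate_svm(X, y, folds, C=C)
    return pooled.auc


def permutation_test(
    F: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    folds: FoldPlan,
    n_perm: int = 1000,
    seed: int = 0,
    C: float = 1.0,
    pipeline=None,
    max_retries: int = 5,
) -> PermutationResult:
    """Label-permutation null distribution of the cross-validated AUC.

    The features and fold plan are held fixed; each replicate permutes the
    full label vector uniformly at random and reruns the evaluation
    pipeline.  A replicate that fails (e.g. a degenerate permutation) is
    retried with fresh randomness up to ``max_retries`` times.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = F.X.astype(float) if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    y = np.asarray(y)
    if pipeline is None:
        pipeline = lambda Xp, yp: _default_pipeline(Xp, yp, folds, C)  # noqa: E731
    observed = pipeline(X, y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        for attempt in range(max_retries + 1):
            perm = rng.permutation(y.size)
            try:
                null[i] = pipeline(X, y[perm])
                break
            except Exception:  # noqa: BLE001 - retry with next draw
                if attempt == max_retries:
                    raise
    return PermutationResult(null_auc=null, observed_auc=float(observed), n_perm=n_perm)


def svm_weight_vector(model: ClassifierModel, X_train: np.ndarray) -> np.ndarray:
    """Voxel weights g = |sum_i alpha_i y_i x_i| from the SVM dual.

    Equals the element-wise absolute value of the primal normal h.
    """
    if model.alpha_signed is None:
        raise ValueError("model is missing dual coefficients")
    X_train = np.asarray(X_train, dtype=float)
    return np.abs(X_train.T @ model.alpha_signed)


def bootstrap_weight_map(
    F: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    frac: float = 0.9,
    C: float = 1.0,
    seed: int = 0,
) -> WeightMap:
    """Mean voxel-weight vector over subsampled SVM retrainings.

    Each replicate draws ``floor(frac * n)`` subjects without replacement
    (redrawn if a class is lost), trains the SVM, and records
    g = |sum alpha_i y_i x_i|; the map is the replicate mean.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    X = F.X.astype(float) if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    y = np.asarray(y)
    n = y.size
    m = int(np.floor(frac * n))
    if m < 2:
        raise ValueError("too few subjects per replicate")
    rng = np.random.default_rng(seed)
    g_sum = np.zeros(X.shape[1])
    for _ in range(n_boot):
        for _attempt in range(100):
            idx = rng.choice(n, size=m, replace=False)
            if np.unique(y[idx]).size == 2:
                break
        else:
            raise ValueError("could not draw a replicate containing both classes")
        model = train_svm(X[idx], y[idx], C=C)
        g_sum += svm_weight_vector(model, X[idx])
    return WeightMap(g_bar=g_sum / n_boot, n_boot=n_boot)


def weight_map_to_volume(wmap: WeightMap, F: FeatureMatrix) -> np.ndarray:
    """Scatter g_bar back onto the grid (zeros at removed/constant voxels)."""
    vol = np.zeros(F.grid.n_voxels)
    vol[F.voxel_index] = wmap.g_bar
    return vol.reshape(F.grid.shape, order=FLATTEN_ORDER)


def cluster_report(
    wmap: WeightMap,
    F: FeatureMatrix,
    threshold_quantile: float = 0.999,
    min_size: int = 100,
) -> pd.DataFrame:
    """Connected clusters of high-weight voxels in world coordinates.

    Voxels with weight above the given quantile (computed over the map's
    features) are grouped by 26-connectivity; clusters below ``min_size``
    voxels are dropped.  Each row reports the cluster id, voxel count,
    hemisphere (sign of the centroid world x; x < 0 is left, midline goes
    right), and the centroid's world-mm coordinates.
    """
    if not 0.0 < threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must be in (0, 1)")
    # 'higher' makes the threshold conservative and sends the table to
    # empty as the quantile approaches 1
    thr = np.quantile(wmap.g_bar, threshold_quantile, method="higher")
    vol = weight_map_to_volume(wmap, F)
    supra = np.zeros(F.grid.shape, dtype=bool)
    ijk = np.unravel_index(F.voxel_index, F.grid.shape, order=FLATTEN_ORDER)
    supra[ijk] = wmap.g_bar > thr
    labeled, n_comp = ndimage.label(supra, structure=np.ones((3, 3, 3), dtype=int))
    rows = []
    cid = 0
    for comp in range(1, n_comp + 1):
        members = np.argwhere(labeled == comp)
        if members.shape[0] < min_size:
            continue
        cid += 1
        lin = np.ravel_multi_index(members.T, F.grid.shape, order=FLATTEN_ORDER)
        world = np.stack([voxel_to_mni(F.grid, int(i)) for i in lin])
        centroid = world.mean(axis=0)
        rows.append(
            {
                "cluster": cid,
                "voxels": int(members.shape[0]),
                "hemisphere": "L" if centroid[0] < 0 else "R",
                "x": centroid[0],
                "y": centroid[1],
                "z": centroid[2],
            }
        )
    return pd.DataFrame(rows, columns=["cluster", "voxels", "hemisphere", "x", "y", "z"])
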