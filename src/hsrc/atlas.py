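"""Atlas-restricted features and per-region classification.

Given an anatomical (AAL-style) or functional (resting-state-network style)
label volume on the working grid, each labeled region's surviving voxels
form a feature submatrix, and a linear SVM is cross-validated per region to
rank regions by their discriminative ability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import FoldPlan, cross_validate_svm
from .volumes import FLATTEN_ORDER, FeatureMatrix, LabelVolume

__all__ = ["AtlasSpec", "region_features", "per_region_classification"]


@dataclass
class AtlasSpec:
    """A label volume plus display names for its regions (background = 0)."""

    volume: LabelVolume
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.region_ids
        if (ids <= 0).any():
            raise ValueError("region ids must be > background (0)")

    @property
    def region_ids(self) -> np.ndarray:
        return np.unique(self.volume.labels[self.volume.labels > 0])

    def name(self, region_id: int) -> str:
        return self.names.get(int(region_id), f"region_{int(region_id)}")

    @classmethod
    def from_files(cls, volume: LabelVolume, lookup_csv=None) -> "AtlasSpec":
        """Build from a label volume and an optional id,name CSV lookup."""
        names = {}
        if lookup_csv is not None:
            table = pd.read_csv(lookup_csv)
            names = dict(zip(table["id"].astype(int), table["name"].astype(str)))
        return cls(volume=volume, names=names)


def region_features(F: FeatureMatrix, atlas: AtlasSpec, region_id: int) -> FeatureMatrix:
    """Submatrix of the columns whose voxel carries the region's label."""
    if atlas.volume.grid.shape != F.grid.shape:
        raise ValueError("atlas grid does not match feature-matrix grid")
    if int(region_id) not in atlas.region_ids:
        raise ValueError(f"region id {region_id} absent from atlas")
    flat = atlas.volume.labels.ravel(order=FLATTEN_ORDER)
    member = flat[F.voxel_index] == int(region_id)
    cols = np.flatnonzero(member)
    return FeatureMatrix(
        X=F.X[:, cols],
        voxel_index=F.voxel_index[cols],
        grid=F.grid,
        subject_ids=list(F.subject_ids),
    )


def per_region_classification(
    F: FeatureMatrix,
    atlas: AtlasSpec,
    y: np.ndarray,
    folds: FoldPlan,
    C: float = 1.0,
    include_unassigned: bool = True,
) -> pd.DataFrame:
    """Cross-validated SVM accuracy/AUC for every atlas region.

    Each region uses all of its surviving voxels directly (no feature
    selection).  Regions without features get null (NaN) metrics.  The
    table is sorted by mean accuracy, best first; an ``unassigned``
    pseudo-region counts mask voxels outside every atlas label.
    """
    if atlas.volume.grid.shape != F.grid.shape:
        raise ValueError("atlas grid does not match feature-matrix grid")
    y = np.asarray(y)
    flat = atlas.volume.labels.ravel(order=FLATTEN_ORDER)
    rows = []
    for rid in atlas.region_ids:
        sub = region_features(F, atlas, int(rid))
        if sub.n_features == 0:
            rows.append(
                {
                    "region_id": int(rid),
                    "name": atlas.name(rid),
                    "n_features": 0,
                    "mean_accuracy": np.nan,
                    "mean_auc": np.nan,
                    "fold_accuracy": [],
                }
            )
            continue
        per_fold, _ = cross_validate_svm(sub.X.astype(float), y, folds, C=C)
        accs = [r.accuracy for r in per_fold]
        rows.append(
            {
                "region_id": int(rid),
                "name": atlas.name(rid),
                "n_features": sub.n_features,
                "mean_accuracy": float(np.mean(accs)),
                "mean_auc": float(np.mean([r.auc for r in per_fold])),
                "fold_accuracy": accs,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "mean_accuracy", ascending=False, na_position="last", kind="stable"
    )
    if include_unassigned:
        n_unassigned = int(np.sum(flat[F.voxel_index] == 0))
        table.attrs["n_unassigned_features"] = n_unassigned
    return table.reset_index(drop=True)
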