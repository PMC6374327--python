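"""Volumes, masks, resolution pyramids and feature matrices.

Binary cortical morphology is represented as a 0/1 volume on a metric grid:
gray-matter voxels are 1, everything else 0.  The classification cascade
operates on a factor-2 resolution pyramid of such volumes, with exact
parent/child voxel bookkeeping so that features selected at a coarse
resolution can be expanded to their fine-resolution children.

All linear voxel indices used for provenance follow Fortran ("F") flattening
order — the first axis varies fastest — with 0-based voxel indices feeding
the NIfTI affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Grid",
    "LabelVolume",
    "BinaryVolume",
    "ResolutionPyramid",
    "FeatureMatrix",
    "load_label_volume",
    "write_volume",
    "extract_cortical_mask",
    "downsample_binary",
    "build_pyramid",
    "assemble_feature_matrix",
    "voxel_to_mni",
]

FLATTEN_ORDER = "F"  # first axis fastest; fixed for cross-module provenance


@dataclass(frozen=True)
class Grid:
    """A 3-D voxel grid with a metric (world-mm) coordinate frame.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts per axis (nx, ny, nz).
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm transform (NIfTI convention, 0-based
        indices).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def __hash__(self) -> int:
        return hash(self.shape)


@dataclass
class LabelVolume:
    """Integer parcellation labels on a grid (e.g. a wmparc volume)."""

    grid: Grid
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid shape")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("labels must be integer-valued")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")


@dataclass
class BinaryVolume:
    """A subject's 0/1 morphology mask on a metric grid."""

    grid: Grid
    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.mask = mask.astype(np.uint8)

    def flat(self) -> np.ndarray:
        """Flattened mask in the package-wide flattening order."""
        return self.mask.ravel(order=FLATTEN_ORDER)


def load_label_volume(path) -> LabelVolume:
    """Load an integer-valued NIfTI parcellation.

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If voxel values deviate from integers by more than 1e-6.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    rounded = np.rint(data)
    if np.abs(data - rounded).max() > 1e-6:
        raise ValueError(f"{path}: voxel values are not integral")
    grid = Grid(shape=tuple(data.shape), affine=np.asarray(img.affine))
    return LabelVolume(grid=grid, labels=rounded.astype(np.int64))


def write_volume(vol: LabelVolume | BinaryVolume, path, dtype=None) -> None:
    """Write a volume to NIfTI-1, preserving the grid affine."""
    data = vol.labels if isinstance(vol, LabelVolume) else vol.mask
    if dtype is None:
        dtype = np.int16 if isinstance(vol, LabelVolume) else np.uint8
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), vol.grid.affine)
    nib.save(img, str(path))


def load_binary_volume(path) -> BinaryVolume:
    """Load a NIfTI volume expected to contain only 0/1 values."""
    lab = load_label_volume(path)
    return BinaryVolume(grid=lab.grid, mask=lab.labels)


def extract_cortical_mask(parc: LabelVolume, lo: int, hi: int) -> BinaryVolume:
    """Binarize a parcellation: 1 where lo <= label <= hi (inclusive).

    The cortical gray-matter labels of a FreeSurfer-style wmparc occupy a
    contiguous integer range (251-2035 in the standard lookup table); both
    endpoints are included.
    """
    if lo > hi:
        raise ValueError(f"lo ({lo}) must be <= hi ({hi})")
    mask = ((parc.labels >= lo) & (parc.labels <= hi)).astype(np.uint8)
    return BinaryVolume(grid=parc.grid, mask=mask)


def _block_view_sums(mask: np.ndarray, factor: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-block 1-counts and block sizes under ceil-division blocking."""
    shape = mask.shape
    out_shape = tuple(-(-s // factor) for s in shape)
    padded_shape = tuple(o * factor for o in out_shape)
    padded = np.zeros(padded_shape, dtype=np.int64)
    padded[: shape[0], : shape[1], : shape[2]] = mask
    counts = padded.reshape(
        out_shape[0], factor, out_shape[1], factor, out_shape[2], factor
    ).sum(axis=(1, 3, 5))
    # actual block sizes (edge blocks may be truncated)
    sizes = np.ones(out_shape, dtype=np.int64)
    for ax, (s, o) in enumerate(zip(shape, out_shape)):
        edge = s - (o - 1) * factor
        ax_sizes = np.full(o, factor, dtype=np.int64)
        ax_sizes[-1] = edge
        sh = [1, 1, 1]
        sh[ax] = o
        sizes = sizes * ax_sizes.reshape(sh)
    return counts, sizes


def downsample_binary(
    vol: BinaryVolume, factor: int = 2, rule: str = "majority"
) -> BinaryVolume:
    """Aggregate a binary volume over factor^3 blocks.

    Rules
    -----
    majority (default)
        Output voxel is 1 iff at least half of its source block is 1
        (ties round to 1; truncated edge blocks use their actual size).
    any / all
        Output is 1 iff any / every source voxel is 1.

    The affine is rescaled so each output voxel's world coordinate is the
    center of its source block.
    """
    if factor < 2:
        raise ValueError("factor must be >= 2")
    counts, sizes = _block_view_sums(vol.mask, factor)
    if rule == "majority":
        out = (2 * counts >= sizes).astype(np.uint8)
    elif rule == "any":
        out = (counts > 0).astype(np.uint8)
    elif rule == "all":
        out = (counts == sizes).astype(np.uint8)
    else:
        raise ValueError(f"unknown downsampling rule {rule!r}")
    affine = vol.grid.affine.copy()
    affine[:3, :3] *= factor
    shift = np.full(3, (factor - 1) / 2.0)
    affine[:3, 3] = vol.grid.affine[:3, :3] @ shift + vol.grid.affine[:3, 3]
    grid = Grid(shape=out.shape, affine=affine)
    return BinaryVolume(grid=grid, mask=out)


@dataclass
class ResolutionPyramid:
    """Nested factor-2 grids with exact parent/child voxel maps.

    ``levels[0]`` is the finest grid; each coarser grid has shape
    ``ceil(previous / 2)`` per axis.  Fine voxel (i, j, k) at level ``l``
    maps to parent (i//2, j//2, k//2) at level ``l + 1``; an interior
    coarse voxel therefore has exactly 8 children (fewer on truncated
    edges).  Linear indices use the package flattening order.
    """

    levels: list[Grid]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def _check_level(self, level: int, coarse_ok: bool = False) -> None:
        top = self.n_levels - 1 if coarse_ok else self.n_levels - 2
        if not 0 <= level <= top:
            raise IndexError(f"level {level} out of range")

    def parent_of(self, level: int, linear_index) -> np.ndarray | int:
        """Map level-``level`` linear voxel indices to level ``level + 1``."""
        self._check_level(level)
        fine, coarse = self.levels[level], self.levels[level + 1]
        idx = np.asarray(linear_index)
        ijk = np.unravel_index(idx, fine.shape, order=FLATTEN_ORDER)
        parent = tuple(c // 2 for c in ijk)
        out = np.ravel_multi_index(parent, coarse.shape, order=FLATTEN_ORDER)
        return out if idx.ndim else int(out)

    def children_of(self, level: int, linear_index: int) -> np.ndarray:
        """Linear indices at level ``level`` of one level-``level + 1`` voxel."""
        self._check_level(level)
        fine, coarse = self.levels[level], self.levels[level + 1]
        ci, cj, ck = np.unravel_index(linear_index, coarse.shape, order=FLATTEN_ORDER)
        ii = [i for i in (2 * ci, 2 * ci + 1) if i < fine.shape[0]]
        jj = [j for j in (2 * cj, 2 * cj + 1) if j < fine.shape[1]]
        kk = [k for k in (2 * ck, 2 * ck + 1) if k < fine.shape[2]]
        grid_i, grid_j, grid_k = np.meshgrid(ii, jj, kk, indexing="ij")
        out = np.ravel_multi_index(
            (grid_i.ravel(), grid_j.ravel(), grid_k.ravel()),
            fine.shape,
            order=FLATTEN_ORDER,
        )
        return np.sort(out)

    def children_of_many(self, level: int, linear_indices) -> np.ndarray:
        """Sorted union of children of several coarse voxels."""
        parts = [self.children_of(level, int(i)) for i in np.asarray(linear_indices)]
        if not parts:
            return np.array([], dtype=np.int64)
        return np.unique(np.concatenate(parts))


def build_pyramid(fine: Grid, n_levels: int) -> ResolutionPyramid:
    """Build an ``n_levels``-deep factor-2 pyramid above a fine grid."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    levels = [fine]
    for _ in range(n_levels - 1):
        prev = levels[-1]
        shape = tuple(-(-s // 2) for s in prev.shape)
        affine = prev.affine.copy()
        affine[:3, :3] *= 2
        affine[:3, 3] = prev.affine[:3, :3] @ np.full(3, 0.5) + prev.affine[:3, 3]
        levels.append(Grid(shape=shape, affine=affine))
    return ResolutionPyramid(levels=levels)


@dataclass
class FeatureMatrix:
    """Subjects x voxel-features binary design matrix with provenance.

    Rows are subjects; columns are the voxels that are neither all-0 nor
    all-1 across subjects.  ``voxel_index[j]`` is the linear index (package
    flattening order) of column ``j`` in ``grid``.
    """

    X: np.ndarray
    voxel_index: np.ndarray
    grid: Grid
    subject_ids: list

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.uint8)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != self.voxel_index.size:
            raise ValueError("voxel_index length must equal number of columns")
        if len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("subject_ids length must equal number of rows")
        if np.unique(self.voxel_index).size != self.voxel_index.size:
            raise ValueError("voxel_index entries must be unique")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def restrict(self, voxel_ids) -> "FeatureMatrix":
        """Submatrix of the columns whose voxel index is in ``voxel_ids``.

        Columns are returned in ascending voxel-index order; requested
        voxels absent from the matrix (removed as constant) are dropped.
        """
        wanted = np.unique(np.asarray(voxel_ids, dtype=np.int64))
        cols = np.flatnonzero(np.isin(self.voxel_index, wanted))
        order = np.argsort(self.voxel_index[cols], kind="stable")
        cols = cols[order]
        return FeatureMatrix(
            X=self.X[:, cols],
            voxel_index=self.voxel_index[cols],
            grid=self.grid,
            subject_ids=list(self.subject_ids),
        )


def assemble_feature_matrix(
    vols: list[BinaryVolume], subject_ids: list
) -> FeatureMatrix:
    """Stack subject masks into a feature matrix, dropping constant columns.

    All volumes must share one grid.  Columns that are all-0 or all-1
    across subjects carry no between-subject information and are removed;
    ``voxel_index`` records the survivors' linear indices.
    """
    if len(vols) < 2:
        raise ValueError("need at least 2 subjects")
    if len(vols) != len(subject_ids):
        raise ValueError("one subject id per volume required")
    grid = vols[0].grid
    for v in vols[1:]:
        if v.grid != grid:
            raise ValueError("all volumes must share an identical grid")
    full = np.stack([v.flat() for v in vols], axis=0)
    col_sums = full.sum(axis=0)
    keep = np.flatnonzero((col_sums > 0) & (col_sums < len(vols)))
    return FeatureMatrix(
        X=full[:, keep],
        voxel_index=keep,
        grid=grid,
        subject_ids=list(subject_ids),
    )


def voxel_to_mni(grid: Grid, linear_index: int) -> np.ndarray:
    """World-mm coordinates of a voxel given by its linear index."""
    if not 0 <= linear_index < grid.n_voxels:
        raise IndexError(f"linear index {linear_index} out of range")
    ijk = np.unravel_index(linear_index, grid.shape, order=FLATTEN_ORDER)
    hom = np.array([ijk[0], ijk[1], ijk[2], 1.0])
    return (grid.affine @ hom)[:3]
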