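"""Synthetic binary-morphology cohorts with known group structure.

The generator emulates the essentials of a cortical-mask cohort on a common
grid: an ellipsoidal shell template standing in for the cortical ribbon,
per-subject jitter of the shell boundary (inter-subject anatomical
variability), and a small number of localized clusters whose voxel-occupancy
probability differs between two groups by a controlled effect size.  Every
downstream module is testable against the implanted ground truth without
any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import FLATTEN_ORDER, BinaryVolume, Grid, write_volume

__all__ = ["SyntheticSpec", "SyntheticCohort", "make_template", "generate_cohort", "write_cohort"]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults describe the reference simulation used throughout the test
    suite: a 32-voxel cube holding an ellipsoidal shell, 100 subjects per
    group, and two implanted clusters in which group +1 voxels are occupied
    with probability ``p_high`` and group -1 with ``p_high - effect_size``.

    Parameters
    ----------
    n_per_group : int
        Subjects per class (cohort size is twice this).
    shape : tuple of int
        Grid voxel counts.
    center, semi_axes : optional
        Ellipsoid center / semi-axes in voxel units; default to the grid
        center and 0.42x the grid shape.
    thickness : float, optional
        Shell thickness in voxels; defaults to half the smallest semi-axis.
    n_clusters : int
        Number of discriminative clusters implanted in the shell.
    cluster_radius : float
        Cluster ball radius in voxels.
    effect_size : float
        Between-group difference in cluster voxel-occupancy probability.
    p_high : float
        Occupancy probability of cluster voxels in group +1.
    cluster_coherence : float
        Fraction of a cluster's voxels that copy a per-subject latent
        cluster state instead of being drawn independently.  0 (the
        default) draws every cluster voxel independently; values > 0
        correlate a cluster's voxels within a subject — emulating a
        regionally coherent morphological effect — while keeping the
        exact designed marginal occupancy per group.
    jitter_rate : float
        Independent flip probability for voxels within one voxel of the
        template boundary (applied per subject).
    seed : int
        RNG seed; the cohort is a pure function of the spec.
    """

    n_per_group: int = 100
    shape: tuple[int, int, int] = (32, 32, 32)
    center: tuple[float, float, float] | None = None
    semi_axes: tuple[float, float, float] | None = None
    thickness: float | None = None
    n_clusters: int = 2
    cluster_radius: float = 3.0
    effect_size: float = 0.6
    p_high: float = 0.9
    cluster_coherence: float = 0.0
    jitter_rate: float = 0.05
    voxel_size_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if self.center is None:
            self.center = tuple((s - 1) / 2.0 for s in self.shape)
        if self.semi_axes is None:
            self.semi_axes = tuple(0.42 * s for s in self.shape)
        if self.thickness is None:
            self.thickness = 0.5 * min(self.semi_axes)
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must be in [0, 1]")
        if not 0.0 <= self.jitter_rate <= 0.5:
            raise ValueError("jitter_rate must be in [0, 0.5]")
        if not 0.0 < self.p_high <= 1.0:
            raise ValueError("p_high must be in (0, 1]")
        if not 0.0 <= self.cluster_coherence <= 1.0:
            raise ValueError("cluster_coherence must be in [0, 1]")
        if self.p_high - self.effect_size < 0.0:
            raise ValueError("p_high - effect_size must be >= 0")
        for c, a, s in zip(self.center, self.semi_axes, self.shape):
            if c - a < -0.5 or c + a > s - 0.5:
                raise ValueError("ellipsoid shell does not fit inside the grid")

    @property
    def grid(self) -> Grid:
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        # center the world origin so hemisphere splits are meaningful
        affine[:3, 3] = -np.asarray(self.center) * self.voxel_size_mm
        return Grid(shape=self.shape, affine=affine)


@dataclass
class SyntheticCohort:
    """Generated volumes, +/-1 labels, and implanted ground-truth voxels."""

    volumes: list[BinaryVolume]
    labels: np.ndarray
    truth_voxels: np.ndarray  # linear indices (package flattening order)
    spec: SyntheticSpec
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.truth_voxels = np.asarray(self.truth_voxels, dtype=np.int64)
        if not self.subject_ids:
            self.subject_ids = [f"S{i:04d}" for i in range(len(self.volumes))]


def _normalized_radius(spec: SyntheticSpec) -> np.ndarray:
    coords = np.meshgrid(*(np.arange(s, dtype=float) for s in spec.shape), indexing="ij")
    rho2 = np.zeros(spec.shape)
    for x, c, a in zip(coords, spec.center, spec.semi_axes):
        rho2 += ((x - c) / a) ** 2
    return np.sqrt(rho2)


def make_template(spec: SyntheticSpec) -> BinaryVolume:
    """Deterministic ellipsoidal-shell template.

    A voxel is in the shell iff its normalized ellipsoidal radius rho lies
    in (1 - thickness/min_semi_axis, 1]; thickness 0 gives an empty mask
    and thickness beyond the smallest semi-axis fills the ellipsoid.
    """
    rho = _normalized_radius(spec)
    lo = 1.0 - spec.thickness / min(spec.semi_axes)
    mask = ((rho <= 1.0) & (rho > lo)).astype(np.uint8)
    return BinaryVolume(grid=spec.grid, mask=mask)


def _cluster_voxels(spec: SyntheticSpec, template: np.ndarray) -> list[np.ndarray]:
    """Pick cluster centers mid-shell and return each ball's shell voxels."""
    if spec.n_clusters == 0:
        return []
    rng = np.random.default_rng(spec.seed + 982_451_653 % 2**31)
    rho = _normalized_radius(spec)
    lo = 1.0 - spec.thickness / min(spec.semi_axes)
    mid, band = (1.0 + lo) / 2.0, (1.0 - lo) / 8.0
    candidates = np.argwhere((np.abs(rho - mid) <= band) & (template == 1))
    if candidates.size == 0:
        raise ValueError("shell too thin to host clusters")
    order = rng.permutation(len(candidates))
    centers: list[np.ndarray] = []
    min_sep = 2 * spec.cluster_radius + 1
    for idx in order:
        c = candidates[idx]
        if all(np.linalg.norm(c - prev) >= min_sep for prev in centers):
            centers.append(c)
        if len(centers) == spec.n_clusters:
            break
    if len(centers) < spec.n_clusters:
        raise ValueError("could not place requested clusters inside the shell")
    coords = np.indices(spec.shape).reshape(3, -1).T
    out = []
    for c in centers:
        dist = np.linalg.norm(coords - c, axis=1)
        in_ball = (dist <= spec.cluster_radius).reshape(spec.shape)
        member = np.argwhere(in_ball & (template == 1))
        out.append(
            np.ravel_multi_index(member.T, spec.shape, order=FLATTEN_ORDER)
        )
    return out


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a reproducible two-group cohort of binary volumes.

    Each subject starts from the shell template; voxels within one voxel of
    the template boundary are flipped independently with ``jitter_rate``;
    cluster voxels are then redrawn with occupancy probability ``p_high``
    (group +1) or ``p_high - effect_size`` (group -1), so truth voxels carry
    exactly the designed effect regardless of jitter.  With
    ``cluster_coherence`` > 0, that fraction of each cluster's voxels copy
    one per-subject latent draw from the same Bernoulli, making the
    cluster a coherent regional feature without changing any marginal
    occupancy.
    """
    template = make_template(spec).mask
    cube = np.ones((3, 3, 3), dtype=bool)
    dil = ndimage.binary_dilation(template.astype(bool), structure=cube)
    ero = ndimage.binary_erosion(template.astype(bool), structure=cube)
    boundary_flat = np.flatnonzero((dil & ~ero).ravel(order=FLATTEN_ORDER))

    clusters = _cluster_voxels(spec, template)
    truth = (
        np.unique(np.concatenate(clusters))
        if clusters
        else np.array([], dtype=np.int64)
    )
    template_flat = template.ravel(order=FLATTEN_ORDER)

    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_group
    labels = np.array([+1] * spec.n_per_group + [-1] * spec.n_per_group)
    p_low = spec.p_high - spec.effect_size
    volumes = []
    for s in range(n):
        flat = template_flat.copy()
        flips = rng.random(boundary_flat.size) < spec.jitter_rate
        flat[boundary_flat[flips]] ^= 1
        p = spec.p_high if labels[s] == +1 else p_low
        for vox in clusters:
            latent = np.uint8(rng.random() < p)
            iid = (rng.random(vox.size) < p).astype(np.uint8)
            coherent = rng.random(vox.size) < spec.cluster_coherence
            flat[vox] = np.where(coherent, latent, iid)
        volumes.append(
            BinaryVolume(
                grid=spec.grid,
                mask=flat.reshape(spec.shape, order=FLATTEN_ORDER),
            )
        )
    return SyntheticCohort(volumes=volumes, labels=labels, truth_voxels=truth, spec=spec)


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict:
    """Write a cohort as NIfTI files + subject CSV + ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, vol, lab in zip(cohort.subject_ids, cohort.volumes, cohort.labels):
        path = out / f"{sid}.nii.gz"
        write_volume(vol, path)
        rows.append({"id": sid, "label": int(lab), "path": path.name})
    table = pd.DataFrame(rows)
    table.to_csv(out / "subjects.csv", index=False)
    spec_echo = asdict(cohort.spec)
    truth = {
        "truth_voxels": [int(v) for v in cohort.truth_voxels],
        "flatten_order": FLATTEN_ORDER,
        "spec": spec_echo,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return {"n_subjects": len(rows), "n_truth_voxels": int(cohort.truth_voxels.size)}
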