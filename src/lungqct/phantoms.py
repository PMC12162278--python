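"""Synthetic phantom generators with analytic ground truth.

Every generator returns the ground truth a downstream module must recover:
tubes carry exact cross-section measures, parenchyma phantoms carry the
realized per-lobe class fractions (count-exact, so recovery tests are exact
rather than stochastic), vessel phantoms carry per-segment volumes,
displacement phantoms carry closed-form deformation tensors, and cohort
simulations are seeded and reproducible. Fixed seed implies bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ellipe

from .airway import AirwaySkeleton, Branch, CrossSectionMeasure
from .deformation import adi as _adi, sri as _sri
from .grid import (
    DisplacementField,
    Grid,
    HUVolume,
    Lobe,
    LobeMask,
    VesselCSAMap,
)

__all__ = [
    "TubePhantomSpec",
    "ParenchymaPhantomSpec",
    "VesselPhantomSpec",
    "AffineFieldSpec",
    "CohortMetricSpec",
    "CohortSimConfig",
    "make_tube_phantom",
    "tube_masks",
    "make_bifurcation_skeleton",
    "make_parenchyma_phantom",
    "make_vessel_phantom",
    "make_affine_displacement",
    "simulate_cohort",
    "GENERATOR_HU_RANGES",
]

# ---------------------------------------------------------------------------
# Tube phantom


@dataclass
class TubePhantomSpec:
    """Straight airway tube: circular or elliptical lumen plus uniform wall.

    For an elliptical lumen (``ellipse_ratio`` = a/b >= 1) the semi-axes are
    chosen as a = r*sqrt(ratio), b = r/sqrt(ratio) so the luminal area equals
    that of the circle of radius ``inner_radius``.
    """

    inner_radius: float  # mm
    wall_thickness_true: float = 1.0  # mm, physical (radial) wall
    length: float = 20.0  # mm
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    ellipse_ratio: float = 1.0  # 1 -> circle
    voxel_spacing: float | tuple[float, float, float] = 0.25  # mm
    lumen_HU: int = -1000
    wall_HU: int = 0
    background_HU: int = -900
    grid_shape: Optional[tuple[int, int, int]] = None  # None -> auto-sized

    def __post_init__(self) -> None:
        if self.inner_radius <= 0:
            raise ValueError("inner_radius must be positive")
        if self.wall_thickness_true < 0:
            raise ValueError("wall_thickness_true must be non-negative")
        if self.ellipse_ratio < 1:
            raise ValueError("ellipse ratio must be >= 1")
        sp = np.broadcast_to(np.asarray(self.voxel_spacing, dtype=float), (3,))
        if np.any(sp <= 0):
            raise ValueError("voxel_spacing must be positive")
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("axis must be a non-zero vector")
        self.axis = tuple(a / n)

    @property
    def semi_axes(self) -> tuple[float, float]:
        s = math.sqrt(self.ellipse_ratio)
        return self.inner_radius * s, self.inner_radius / s


def _ellipse_perimeter(a: float, b: float) -> float:
    # complete elliptic integral of the second kind, scipy parameter m = e^2
    m = 1.0 - (b / a) ** 2
    return 4.0 * a * float(ellipe(m))


def _tube_ground_truth(spec: TubePhantomSpec) -> CrossSectionMeasure:
    a, b = spec.semi_axes
    LA = math.pi * a * b
    Pe = _ellipse_perimeter(a, b) if spec.ellipse_ratio > 1 else 2 * math.pi * spec.inner_radius
    wt = spec.wall_thickness_true
    total = math.pi * (a + wt) * (b + wt)
    D_inner = 2 * math.sqrt(LA / math.pi)
    D_outer = 2 * math.sqrt(total / math.pi)
    return CrossSectionMeasure(LA=LA, P_e=Pe, D_inner=D_inner, D_outer=D_outer,
                               WT=D_outer - D_inner)


def make_tube_phantom(
    spec: TubePhantomSpec,
) -> tuple[HUVolume, AirwaySkeleton, CrossSectionMeasure]:
    """Voxelize the tube, build its single-branch centerline skeleton, and
    return the analytic cross-section ground truth (WT in the
    diameter-difference convention, i.e. twice the physical wall)."""
    sp = np.broadcast_to(np.asarray(spec.voxel_spacing, dtype=float), (3,)).copy()
    grid = Grid(spacing=tuple(sp))
    a, b = spec.semi_axes
    outer = max(a, b) + spec.wall_thickness_true
    margin = 2  # voxels
    # required physical half-extent along each axis
    axis = np.asarray(spec.axis)
    half_needed = np.abs(axis) * spec.length / 2 + outer + margin * sp
    shape_needed = tuple(int(math.ceil(2 * h / s)) + 1 for h, s in zip(half_needed, sp))
    if spec.grid_shape is None:
        shape = shape_needed
    else:
        shape = spec.grid_shape
        if any(s < n for s, n in zip(shape, shape_needed)):
            raise ValueError(
                f"tube exceeds grid: shape {shape} too small, need at least {shape_needed}"
            )

    idx = np.indices(shape, dtype=float)
    world = idx * sp[:, None, None, None]
    centre = (np.array(shape) - 1) * sp / 2
    rel = world - centre[:, None, None, None]
    s_along = np.tensordot(axis, rel, axes=(0, 0))
    radial = rel - axis[:, None, None, None] * s_along[None]
    e1, e2 = _orthobasis(axis)
    x = np.tensordot(e1, radial, axes=(0, 0))
    y = np.tensordot(e2, radial, axes=(0, 0))
    in_len = np.abs(s_along) <= spec.length / 2
    in_lumen = ((x / a) ** 2 + (y / b) ** 2 <= 1.0) & in_len
    wt = spec.wall_thickness_true
    in_total = ((x / (a + wt)) ** 2 + (y / (b + wt)) ** 2 <= 1.0) & in_len

    hu = np.full(shape, spec.background_HU, dtype=np.int16)
    hu[in_total] = spec.wall_HU
    hu[in_lumen] = spec.lumen_HU
    vol = HUVolume(data=hu, grid=grid)

    n_pts = max(int(spec.length / min(sp)), 5)
    t = np.linspace(-spec.length / 2, spec.length / 2, n_pts)
    pts = centre[None, :] + t[:, None] * axis[None, :]
    skel = AirwaySkeleton(
        points=pts,
        edges=[(i, i + 1) for i in range(n_pts - 1)],
        branches=[Branch(label="Trachea", point_ids=list(range(n_pts)))],
    )
    return vol, skel, _tube_ground_truth(spec)


def tube_masks(vol: HUVolume, spec: TubePhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Lumen and wall boolean masks recovered from a tube phantom volume."""
    lumen = vol.data == spec.lumen_HU
    wall = vol.data == spec.wall_HU
    return lumen, wall


def _orthobasis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(axis)))] = 1.0
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# Bifurcation skeleton


def make_bifurcation_skeleton(
    parent_axis: Sequence[float],
    daughter_axes: tuple[Sequence[float], Sequence[float]],
    *,
    branch_length: float = 20.0,
    points_per_branch: int = 11,
    labels: tuple[str, str, str] = ("Trachea", "LMB", "RMB"),
) -> AirwaySkeleton:
    """Three-branch skeleton: a parent ending at the origin and two straight
    daughters leaving it along the given (normalized) directions."""
    p = np.asarray(parent_axis, dtype=float)
    if np.linalg.norm(p) == 0:
        raise ValueError("parent axis must be non-zero")
    p = p / np.linalg.norm(p)
    ds = []
    for d in daughter_axes:
        v = np.asarray(d, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("daughter direction must be non-zero")
        ds.append(v / n)

    t = np.linspace(0, 1, points_per_branch)
    parent_pts = (-branch_length * (1 - t))[:, None] * p[None, :]
    points = [parent_pts]
    n0 = points_per_branch
    branches = [Branch(label=labels[0], point_ids=list(range(n0)))]
    edges = [(i, i + 1) for i in range(n0 - 1)]
    bif_id = n0 - 1  # origin
    offset = n0
    for d, lab in zip(ds, labels[1:]):
        pts = (branch_length * t[1:])[:, None] * d[None, :]
        ids = [bif_id] + list(range(offset, offset + len(pts)))
        points.append(pts)
        branches.append(Branch(label=lab, point_ids=ids))
        edges.extend(zip(ids[:-1], ids[1:]))
        offset += len(pts)
    return AirwaySkeleton(points=np.vstack(points), edges=edges, branches=branches)


# ---------------------------------------------------------------------------
# Parenchyma phantom

#: HU ranges the generator draws from: the open interior of each class range,
#: so classification does not depend on boundary conventions. Filler is the
#: explicit above-60 remainder.
GENERATOR_HU_RANGES: dict[str, tuple[int, int]] = {
    "Emph": (-1000, -952),
    "Norm": (-949, -702),
    "GGO": (-699, -502),
    "Semiconso": (-499, -202),
    "Conso": (-199, 59),
    "_filler": (100, 500),
}


@dataclass
class ParenchymaPhantomSpec:
    """Per-lobe target class fractions; the remainder (1 - sum) becomes
    dense above-60-HU filler."""

    fractions: dict  # lobe name or Lobe -> {class name -> fraction}
    grid_shape: tuple[int, int, int] = (30, 30, 40)
    voxel_spacing: float | tuple[float, float, float] = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        norm: dict[Lobe, dict[str, float]] = {}
        for lobe, fr in self.fractions.items():
            lb = Lobe[lobe] if isinstance(lobe, str) else Lobe(lobe)
            for cls, f in fr.items():
                if cls not in GENERATOR_HU_RANGES or cls == "_filler":
                    raise ValueError(f"unknown parenchymal class {cls!r}")
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"fraction {cls}={f} outside [0, 1]")
            total = sum(fr.values())
            if total > 1.0 + 1e-12:
                raise ValueError(f"fractions for {lb.name} sum to {total} > 1")
            norm[lb] = dict(fr)
        self.fractions = norm


def _lobe_partition(shape: tuple[int, int, int]) -> np.ndarray:
    """Deterministic geometric five-lobe partition with a 1-voxel background
    rim: left/right split along x, upper/lower (and middle on the right)
    along z."""
    labels = np.zeros(shape, dtype=np.uint8)
    nx, ny, nz = shape
    xs = slice(1, nx - 1)
    ys = slice(1, ny - 1)
    zmid = 1 + (nz - 2) // 2
    zthird1 = 1 + (nz - 2) // 3
    zthird2 = 1 + 2 * (nz - 2) // 3
    half_x = nx // 2
    # left lung (x < half): LUL above, LLL below
    labels[xs, ys, 1 : nz - 1] = 0
    labels[1:half_x, ys, zmid : nz - 1] = Lobe.LUL
    labels[1:half_x, ys, 1:zmid] = Lobe.LLL
    # right lung: RUL / RML / RLL by z thirds
    labels[half_x : nx - 1, ys, zthird2 : nz - 1] = Lobe.RUL
    labels[half_x : nx - 1, ys, zthird1:zthird2] = Lobe.RML
    labels[half_x : nx - 1, ys, 1:zthird1] = Lobe.RLL
    return labels


def _largest_remainder_counts(fracs: Sequence[float], n: int) -> list[int]:
    raw = np.asarray(fracs, dtype=float) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts.tolist()


def make_parenchyma_phantom(
    spec: ParenchymaPhantomSpec,
) -> tuple[HUVolume, LobeMask, pd.DataFrame]:
    """Lobe-partitioned HU volume with count-exact class allocation.

    Voxel counts per class are allocated by largest-remainder rounding of
    fraction x N, voxel positions shuffled with the seeded RNG, and HU drawn
    uniformly from the interior of each class range. Returns the realized
    per-lobe fractions (rows = lobes, columns = classes), which equal the
    requested fractions up to count rounding.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _lobe_partition(spec.grid_shape)
    hu = np.full(spec.grid_shape, -1000, dtype=np.int16)  # background: air
    realized_rows = {}
    for lobe in Lobe:
        fr = spec.fractions.get(lobe, {})
        voxels = np.flatnonzero(labels == int(lobe))
        n = voxels.size
        if n == 0:
            continue
        classes = list(fr.keys())
        fracs = [fr[c] for c in classes]
        filler = 1.0 - sum(fracs)
        classes.append("_filler")
        fracs.append(filler)
        counts = _largest_remainder_counts(fracs, n)
        rng.shuffle(voxels)
        pos = 0
        realized = {}
        for cls, cnt in zip(classes, counts):
            lo, hi = GENERATOR_HU_RANGES[cls]
            vals = rng.integers(lo, hi + 1, size=cnt)
            hu.flat[voxels[pos : pos + cnt]] = vals
            pos += cnt
            if cls != "_filler":
                realized[cls] = cnt / n
        realized_rows[lobe.name] = realized
    grid = Grid(spacing=spec.voxel_spacing if np.ndim(spec.voxel_spacing) else
                (float(spec.voxel_spacing),) * 3)
    vol = HUVolume(data=hu, grid=grid)
    mask = LobeMask(data=labels, grid=grid)
    true_fractions = pd.DataFrame(realized_rows).T.fillna(0.0)
    return vol, mask, true_fractions


# ---------------------------------------------------------------------------
# Vessel phantom


@dataclass
class VesselPhantomSpec:
    """Vessel segments as (cross-sectional area mm^2, volume cc) pairs."""

    segments: list[tuple[float, float]]
    grid_shape: tuple[int, int, int] = (40, 40, 60)
    voxel_spacing: float | tuple[float, float, float] = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for area, vol in self.segments:
            if area <= 0:
                raise ValueError(f"cross-sectional area must be positive, got {area}")
            if vol <= 0:
                raise ValueError(f"segment volume must be positive, got {vol}")


def make_vessel_phantom(spec: VesselPhantomSpec) -> VesselCSAMap:
    """Disjoint vessel segments, each tagged with its cross-sectional area;
    realized per-segment volume matches the spec within one voxel volume.
    Segments are laid out consecutively in flat index order (never
    overlapping); an error is raised if they do not fit in the grid."""
    grid = Grid(
        spacing=spec.voxel_spacing if np.ndim(spec.voxel_spacing) else
        (float(spec.voxel_spacing),) * 3
    )
    vv = grid.voxel_volume_mm3 / 1000.0  # cc per voxel
    data = np.zeros(spec.grid_shape, dtype=float)
    n_total = data.size
    pos = 0
    for area, vol_cc in spec.segments:
        n_vox = int(round(vol_cc / vv))
        if pos + n_vox > n_total:
            raise ValueError(
                "vessel segments do not fit without overlap: "
                f"need {pos + n_vox} voxels, grid has {n_total}"
            )
        flat = data.reshape(-1)
        if np.any(flat[pos : pos + n_vox] > 0):
            raise ValueError("overlapping vessel segments")
        flat[pos : pos + n_vox] = area
        pos += n_vox + 1  # 1-voxel gap keeps segments disjoint
    return VesselCSAMap(data=data, grid=grid)


# ---------------------------------------------------------------------------
# Affine displacement phantom


@dataclass
class AffineFieldSpec:
    """Affine deformation x -> A x + t sampled as a displacement field."""

    A: np.ndarray  # 3x3, det > 0
    t: tuple[float, float, float] = (0.0, 0.0, 0.0)
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing: float | tuple[float, float, float] = 1.0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).reshape(3, 3)
        if np.linalg.det(self.A) <= 0:
            raise ValueError("det(A) must be positive (folding field)")


def make_affine_displacement(
    spec: AffineFieldSpec,
) -> tuple[DisplacementField, dict]:
    """Sample u(x) = (A - I) x + t on the grid; the closed-form tensors
    (F = A, J, principal stretches, ADI, SRI) follow from A by direct
    linear algebra and serve as the oracle for the field-based pipeline."""
    grid = Grid(
        spacing=spec.voxel_spacing if np.ndim(spec.voxel_spacing) else
        (float(spec.voxel_spacing),) * 3
    )
    idx = np.indices(spec.grid_shape, dtype=float)
    world = np.stack(
        [idx[i] * grid.spacing[i] + grid.origin[i] for i in range(3)], axis=-1
    )
    u = world @ (spec.A - np.eye(3)).T + np.asarray(spec.t, dtype=float)
    field = DisplacementField(data=u, grid=grid)

    F = spec.A
    J = float(np.linalg.det(F))
    lam = np.sqrt(np.linalg.eigvalsh(F.T @ F))[::-1]
    closed_form = {
        "F": F,
        "J": J,
        "stretches": tuple(float(x) for x in lam),
        "ADI": float(_adi(lam[0], lam[1], lam[2])),
        "SRI": float(_sri(lam[0], lam[1], lam[2])),
    }
    return field, closed_form


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class CohortMetricSpec:
    """Baseline distribution and follow-up effect for one metric.

    followup = baseline * (1 + effect_relative) + effect_additive + noise,
    noise ~ N(0, noise_sd). With both effects 0 the paired differences have
    mean 0 by construction.
    """

    baseline_mean: float
    baseline_sd: float
    effect_relative: float = 0.0
    effect_additive: float = 0.0
    noise_sd: float = 0.0


@dataclass
class CohortSimConfig:
    """Two-visit cohort: n subjects, Gaussian scan intervals truncated at > 0.

    Defaults mirror the study cohort shape: 31 subjects, scan interval
    360.10 +/- 15.38 days.
    """

    metrics: dict  # name -> CohortMetricSpec
    n_subjects: int = 31
    interval_mean: float = 360.10
    interval_sd: float = 15.38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.interval_mean <= 0:
            raise ValueError("interval_mean must be positive")
        if self.interval_sd < 0:
            raise ValueError("interval_sd must be non-negative")


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate a two-visit cohort table with columns
    (subject_id, metric, baseline, followup, interval_days)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    intervals = rng.normal(config.interval_mean, config.interval_sd, size=n)
    for _ in range(100):
        bad = intervals <= 0
        if not bad.any():
            break
        intervals[bad] = rng.normal(config.interval_mean, config.interval_sd, size=bad.sum())
    rows = []
    for name, m in config.metrics.items():
        baseline = rng.normal(m.baseline_mean, m.baseline_sd, size=n)
        noise = rng.normal(0.0, m.noise_sd, size=n) if m.noise_sd > 0 else np.zeros(n)
        followup = baseline * (1.0 + m.effect_relative) + m.effect_additive + noise
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"S{i:03d}",
                    "metric": name,
                    "baseline": baseline[i],
                    "followup": followup[i],
                    "interval_days": intervals[i],
                }
            )
    return pd.DataFrame(rows)
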