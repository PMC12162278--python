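"""Airway morphometry: branch-level structural metrics from a labeled
centerline skeleton plus lumen/wall masks.

The measured quantities follow standard quantitative-CT airway analysis:

* bifurcation angle theta — angle between daughter direction vectors (cosine law);
* hydraulic diameter D_h = 4 LA / P_e;
* circularity Cr = pi D_inner / P_e, equal to 1 for a circular lumen;
* wall thickness WT from the equivalent-area inner and outer diameters.

D_inner is the equivalent-area diameter 2 sqrt(LA/pi) and D_outer the
equivalent-area diameter of lumen + wall, so Cr is exactly 1 for a circle.
WT defaults to the diameter difference D_outer - D_inner (twice the physical
wall); a ``radial`` convention is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.measure import find_contours

from .grid import Grid

__all__ = [
    "BRANCH_REGISTRY",
    "LOBAR_SUBGROUPS",
    "AirwaySkeleton",
    "Branch",
    "CrossSectionMeasure",
    "BranchRecord",
    "bifurcation_angle",
    "hydraulic_diameter",
    "circularity",
    "measure_cross_section",
    "branch_table",
]

# ---------------------------------------------------------------------------
# Branch-label registry

_SEGMENTAL = [f"RB{i}" for i in range(1, 11)] + [f"LB{i}" for i in range(1, 11)]
_COMBINED = ["LB1+2", "LB4+5", "LB9+10", "RB9+10", "LB1+2+3"]
_CENTRAL = ["Trachea", "LMB", "RMB", "Bronint", "TriLUL", "TriRUL", "TriRLL", "TriLLB"]
_SUBGROUP_NAMES = ["LUL", "LLL", "RUL", "RML", "RLL"]

#: Every label a measured branch may carry. Lobar subgroups are aggregate
#: rows computed from member branches, also first-class registry entries.
BRANCH_REGISTRY: frozenset[str] = frozenset(_CENTRAL + _SEGMENTAL + _COMBINED + _SUBGROUP_NAMES)

#: Lobar subgroup -> member branch labels aggregated by arithmetic mean.
LOBAR_SUBGROUPS: dict[str, tuple[str, ...]] = {
    "LUL": ("LB1", "LB2", "LB3", "LB4", "LB5", "LB1+2", "LB4+5", "LB1+2+3"),
    "LLL": ("LB6", "LB7", "LB8", "LB9", "LB10", "LB9+10"),
    "RUL": ("RB1", "RB2", "RB3"),
    "RML": ("RB4", "RB5"),
    "RLL": ("RB6", "RB7", "RB8", "RB9", "RB10", "RB9+10"),
}
# LB7 is commonly absent as an independent branch on the left; it is in the
# membership table so that datasets which do label it aggregate correctly.


@dataclass
class Branch:
    """One airway branch: ordered point ids from proximal to distal end."""

    label: str
    point_ids: list[int]

    def __post_init__(self) -> None:
        if len(self.point_ids) < 2:
            raise ValueError(f"branch {self.label!r} needs at least 2 points")


@dataclass
class AirwaySkeleton:
    """Labeled 1-D airway centerline tree in world coordinates (mm).

    ``points`` is an (N, 3) array; ``edges`` connect point ids; ``branches``
    partition the tree into labeled runs of points, proximal end first.
    """

    points: np.ndarray
    edges: list[tuple[int, int]]
    branches: list[Branch]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("skeleton points must be (N, 3)")

    def branch(self, label: str) -> Branch:
        for b in self.branches:
            if b.label == label:
                return b
        raise KeyError(f"no branch labeled {label!r}")

    def branch_points(self, branch: Branch) -> np.ndarray:
        return self.points[branch.point_ids]

    def children_of(self, branch: Branch) -> list[Branch]:
        """Branches whose proximal point coincides with this branch's distal point."""
        tip = branch.point_ids[-1]
        out = []
        for b in self.branches:
            if b is branch:
                continue
            if b.point_ids[0] == tip:
                out.append(b)
        return out

    def direction_vector(self, branch: Branch, fraction: float = 0.3) -> np.ndarray:
        """Unit vector from the branch origin toward the point ``fraction`` of
        the way along its arclength (default 30%; short spans are noise-
        sensitive, full spans bend-sensitive)."""
        pts = self.branch_points(branch)
        target = _point_at_arclength_fraction(pts, fraction)
        d = target - pts[0]
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError(f"degenerate branch {branch.label!r}: zero-length span")
        return d / n

    def validate(self) -> list[str]:
        """Structural checks; returns a list of violation strings (empty = OK)."""
        issues = []
        n = len(self.points)
        if self.edges:
            seen = {i for e in self.edges for i in e}
            if max(seen) >= n:
                issues.append("edge references point id beyond point array")
            if len(self.edges) != n - 1:
                issues.append(f"tree must have N-1 edges ({n - 1}), found {len(self.edges)}")
        for b in self.branches:
            if b.label not in BRANCH_REGISTRY:
                issues.append(f"unknown branch label {b.label!r}")
        return issues


def _point_at_arclength_fraction(pts: np.ndarray, fraction: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return pts[-1]
    s = np.clip(fraction, 0.0, 1.0) * total
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg) - 1)
    t = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    return pts[i] + t * (pts[i + 1] - pts[i])


def _tangent_at_fraction(pts: np.ndarray, fraction: float) -> np.ndarray:
    eps = 0.02
    a = _point_at_arclength_fraction(pts, max(fraction - eps, 0.0))
    b = _point_at_arclength_fraction(pts, min(fraction + eps, 1.0))
    d = b - a
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("cannot estimate tangent: degenerate centerline span")
    return d / n


# ---------------------------------------------------------------------------
# Scalar metrics


@dataclass
class CrossSectionMeasure:
    """Cross-sectional lumen/wall measurements at one centerline station."""

    LA: float  # luminal area, mm^2
    P_e: float  # luminal perimeter, mm
    D_inner: float  # equivalent-area inner diameter, mm
    D_outer: float  # equivalent-area outer (lumen+wall) diameter, mm; NaN if no wall mask
    WT: float  # wall thickness per convention; NaN if no wall mask

    def __post_init__(self) -> None:
        if self.LA <= 0:
            raise ValueError("luminal area must be positive")
        if self.P_e < 2.0 * math.sqrt(math.pi * self.LA) * (1 - 1e-9):
            raise ValueError(
                "isoperimetric violation: perimeter smaller than a circle of equal area"
            )


@dataclass
class BranchRecord:
    """Tabulated per-branch metrics; theta only where a daughter pair exists."""

    label: str
    theta: Optional[float]  # degrees
    Dh: float  # mm
    WT: float  # mm (NaN when no wall mask)
    Cr: float
    LA: float = math.nan
    Pe: float = math.nan


def bifurcation_angle(d1: Sequence[float], d2: Sequence[float]) -> float:
    """Angle (degrees) between two daughter direction vectors by the cosine law.

    Symmetric in its arguments and invariant under a common rotation; the
    cosine is clamped to [-1, 1] against floating-point overshoot.
    """
    v1 = np.asarray(d1, dtype=float)
    v2 = np.asarray(d2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("direction vectors must be non-zero")
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(c))


def hydraulic_diameter(LA: float, P_e: float) -> float:
    """D_h = 4 LA / P_e (mm): effective duct diameter for flow."""
    if LA <= 0 or P_e <= 0:
        raise ValueError("LA and P_e must be positive")
    return 4.0 * LA / P_e


def circularity(D_inner: float, P_e: float) -> float:
    """Cr = pi D_inner / P_e; equals 1 when the lumen is a circle and
    D_inner its equivalent-area diameter."""
    if D_inner <= 0 or P_e <= 0:
        raise ValueError("D_inner and P_e must be positive")
    return math.pi * D_inner / P_e


# ---------------------------------------------------------------------------
# Sub-pixel cross-section measurement


def _plane_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(tangent)))] = 1.0
    e1 = np.cross(tangent, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(tangent, e1)
    return e1, e2


def _contour_metrics(
    plane: np.ndarray, res: float, center_px: float
) -> tuple[float, float]:
    """Area (mm^2) and perimeter (mm) of the 0.5-level contour enclosing the
    plane center. Raises if no contour encloses the center or the section is
    not simply connected."""
    contours = [c for c in find_contours(plane, 0.5) if np.allclose(c[0], c[-1])]
    center = (center_px, center_px)
    enclosing = [c for c in contours if MplPath(c).contains_point(center)]
    if not enclosing:
        raise ValueError("cross-section plane misses the lumen (no enclosing contour)")
    # innermost enclosing contour bounds the section; anything nested inside
    # it is a hole -> not simply connected.
    main = min(enclosing, key=lambda c: _shoelace(c))
    holes = [
        c
        for c in contours
        if c is not main
        and _shoelace(c) > 1.0  # ignore sub-pixel speckle
        and MplPath(main).contains_point(c.mean(axis=0))
    ]
    if holes:
        raise ValueError("lumen cross-section is not simply connected")
    area = _shoelace(main) * res * res
    perim = float(np.sum(np.linalg.norm(np.diff(main, axis=0), axis=1))) * res
    return area, perim


def _shoelace(c: np.ndarray) -> float:
    x, y = c[:, 0], c[:, 1]
    return 0.5 * abs(float(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1])))


def _sample_plane(
    mask: np.ndarray,
    grid: Grid,
    center: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    halfwidth: float,
    res: float,
    smooth_sigma_mm: float,
) -> tuple[np.ndarray, float]:
    m = 2 * int(math.ceil(halfwidth / res)) + 1
    u = (np.arange(m) - (m - 1) / 2) * res
    world = (
        center[None, None, :]
        + u[:, None, None] * e1[None, None, :]
        + u[None, :, None] * e2[None, None, :]
    )
    idx = grid.world_to_index(world.reshape(-1, 3)).T.reshape(3, m, m)
    plane = map_coordinates(mask.astype(float), idx, order=1, mode="constant", cval=0.0)
    if smooth_sigma_mm > 0:
        plane = gaussian_filter(plane, smooth_sigma_mm / res)
    return plane, (m - 1) / 2


def measure_cross_section(
    lumen_mask: np.ndarray,
    wall_mask: Optional[np.ndarray],
    grid: Grid,
    skeleton: AirwaySkeleton,
    branch: str | Branch,
    station: float = 0.5,
    *,
    upsample: int = 4,
    wt_convention: Literal["diameter_difference", "radial"] = "diameter_difference",
    plane_halfwidth_mm: Optional[float] = None,
    smooth_sigma_vox: float = 1.0,
) -> CrossSectionMeasure:
    """Measure LA, P_e, D_inner, D_outer and WT on the plane orthogonal to the
    centerline at ``station`` (arclength fraction in [0, 1]) of ``branch``.

    The plane is resampled at ``min(spacing)/upsample`` with linear
    interpolation, smoothed with a Gaussian of ``smooth_sigma_vox`` voxel
    spacings (suppresses the jagged-boundary perimeter bias of a binary
    mask), and the lumen boundary extracted as the sub-pixel 0.5-level
    contour. D_inner/D_outer are equivalent-area diameters.
    """
    if not 0.0 <= station <= 1.0:
        raise ValueError("station must be an arclength fraction in [0, 1]")
    b = skeleton.branch(branch) if isinstance(branch, str) else branch
    pts = skeleton.branch_points(b)
    center = _point_at_arclength_fraction(pts, station)
    tangent = _tangent_at_fraction(pts, station)
    e1, e2 = _plane_basis(tangent)

    total_mask = lumen_mask if wall_mask is None else (lumen_mask | wall_mask)
    if plane_halfwidth_mm is None:
        occ = np.argwhere(total_mask)
        if occ.size == 0:
            raise ValueError("empty lumen mask")
        span = (occ.max(axis=0) - occ.min(axis=0) + 1) * np.array(grid.spacing)
        plane_halfwidth_mm = 0.75 * float(span.max()) + 2 * max(grid.spacing)
    res = min(grid.spacing) / upsample
    sigma_mm = smooth_sigma_vox * min(grid.spacing)

    try:
        plane, c_px = _sample_plane(
            lumen_mask, grid, center, e1, e2, plane_halfwidth_mm, res, sigma_mm
        )
        LA, Pe = _contour_metrics(plane, res, c_px)
    except ValueError as err:
        raise ValueError(f"branch {b.label!r} station {station}: {err}") from None

    D_inner = 2.0 * math.sqrt(LA / math.pi)
    if wall_mask is not None:
        tplane, c_px = _sample_plane(
            total_mask, grid, center, e1, e2, plane_halfwidth_mm, res, sigma_mm
        )
        total_area, _ = _contour_metrics(tplane, res, c_px)
        D_outer = 2.0 * math.sqrt(total_area / math.pi)
        WT = D_outer - D_inner
        if wt_convention == "radial":
            WT = WT / 2.0
        elif wt_convention != "diameter_difference":
            raise ValueError(f"unknown wt_convention {wt_convention!r}")
    else:
        D_outer = math.nan
        WT = math.nan
    return CrossSectionMeasure(LA=LA, P_e=Pe, D_inner=D_inner, D_outer=D_outer, WT=WT)


# ---------------------------------------------------------------------------
# Branch table


def branch_table(
    skeleton: AirwaySkeleton,
    lumen_mask: np.ndarray,
    wall_mask: Optional[np.ndarray],
    grid: Grid,
    *,
    station: float = 0.5,
    direction_fraction: float = 0.3,
    wt_convention: Literal["diameter_difference", "radial"] = "diameter_difference",
) -> list[BranchRecord]:
    """One record per labeled branch plus one aggregate record per lobar
    subgroup with members present. Metrics are measured mid-branch by
    default; theta is attached to a branch with >= 2 daughters (mean of
    pairwise daughter angles at a trifurcation)."""
    unknown = sorted({b.label for b in skeleton.branches} - BRANCH_REGISTRY)
    if unknown:
        raise ValueError(f"unknown branch labels: {unknown}")

    records: list[BranchRecord] = []
    for b in skeleton.branches:
        m = measure_cross_section(
            lumen_mask, wall_mask, grid, skeleton, b,
            station=station, wt_convention=wt_convention,
        )
        children = skeleton.children_of(b)
        theta = None
        if len(children) >= 2:
            dirs = [skeleton.direction_vector(c, direction_fraction) for c in children]
            pair_angles = [
                bifurcation_angle(dirs[i], dirs[j])
                for i in range(len(dirs))
                for j in range(i + 1, len(dirs))
            ]
            theta = float(np.mean(pair_angles))
        records.append(
            BranchRecord(
                label=b.label,
                theta=theta,
                Dh=hydraulic_diameter(m.LA, m.P_e),
                WT=m.WT,
                Cr=circularity(m.D_inner, m.P_e),
                LA=m.LA,
                Pe=m.P_e,
            )
        )

    by_label = {r.label: r for r in records}
    for sub, members in LOBAR_SUBGROUPS.items():
        present = [by_label[name] for name in members if name in by_label]
        if not present:
            continue
        records.append(
            BranchRecord(
                label=sub,
                theta=None,
                Dh=float(np.mean([r.Dh for r in present])),
                WT=float(np.mean([r.WT for r in present])),
                Cr=float(np.mean([r.Cr for r in present])),
                LA=float(np.mean([r.LA for r in present])),
                Pe=float(np.mean([r.Pe for r in present])),
            )
        )
    return records


def records_to_frame(records: list[BranchRecord]):
    """Branch records as a DataFrame with the canonical output columns."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "label": r.label,
                "theta_deg": r.theta,
                "Dh_mm": r.Dh,
                "WT_mm": r.WT,
                "Cr": r.Cr,
                "LA_mm2": r.LA,
                "Pe_mm": r.Pe,
            }
            for r in records
        ]
    )
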