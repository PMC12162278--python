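"""Registration-derived deformation metrics.

From a displacement field u(x) in the fixed-image frame (baseline fixed,
follow-up moving), the per-voxel deformation gradient is F = I + grad(u)
with spacing-aware central differences. Derived scalars:

* J = det F — local volume-change ratio (> 1 expansion, < 1 contraction);
* principal stretches lambda_1 >= lambda_2 >= lambda_3, the square roots of
  the eigenvalues of F^T F;
* ADI = sqrt(((l1-l2)/l2)^2 + ((l2-l3)/l3)^2) — magnitude of directional
  preference (0 for isotropic deformation);
* SRI = (2/pi) atan2((l1-l2)/l2, (l2-l3)/l3) in [0, 1] — 0 for slab-like
  (l1 = l2 > l3), 1 for rod-like (l1 > l2 = l3) deformation.

The ADI/SRI formulas are the standard eigen-stretch ratio indices for
registration-based lung deformation; the polarity (0 = slab, 1 = rod) is a
package convention stamped into output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import DisplacementField, LobeMask, REGIONS

__all__ = [
    "deformation_gradient",
    "jacobian",
    "principal_stretches",
    "adi",
    "sri",
    "compute_tensors",
    "DeformationTensors",
    "regional_summary",
    "METRIC_PROVENANCE",
]

#: stamped into outputs alongside regional summaries
METRIC_PROVENANCE = {
    "adi_formula": "sqrt(((l1-l2)/l2)^2 + ((l2-l3)/l3)^2)",
    "sri_formula": "(2/pi)*atan2((l1-l2)/l2, (l2-l3)/l3)",
    "sri_polarity": "0=slab-like, 1=rod-like",
    "gradient": "central differences in world mm, one-sided at boundaries",
}


def deformation_gradient(field: DisplacementField) -> np.ndarray:
    """Per-voxel F = I + grad(u), shape (nx, ny, nz, 3, 3); derivatives taken
    in world units so anisotropic spacing does not bias F. Central
    differences are exact for affine fields at interior voxels."""
    shape = field.shape
    if min(shape) < 3:
        raise ValueError(f"field needs >= 3 voxels per axis, got {shape}")
    F = np.empty(shape + (3, 3))
    for i in range(3):
        grads = np.gradient(field.data[..., i], *field.grid.spacing, axis=(0, 1, 2))
        for j in range(3):
            F[..., i, j] = grads[j]
        F[..., i, i] += 1.0
    return F


def jacobian(F: np.ndarray) -> np.ndarray:
    """J = det(F): local volume-change ratio."""
    return np.linalg.det(np.asarray(F, dtype=float))


def principal_stretches(F: np.ndarray) -> np.ndarray:
    """Principal stretches sorted descending along the last axis.

    Computed as square roots of the eigenvalues of the right Cauchy-Green
    tensor C = F^T F. Voxels with non-positive eigenvalues (folded field)
    come out as NaN and are excluded from summaries.
    """
    F = np.asarray(F, dtype=float)
    C = np.swapaxes(F, -1, -2) @ F
    ev = np.linalg.eigvalsh(C)  # ascending
    ev = ev[..., ::-1]
    with np.errstate(invalid="ignore"):
        lam = np.where(ev > 0, np.sqrt(np.abs(ev)), np.nan)
    return lam


def _check_sorted(l1, l2, l3) -> None:
    l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
    valid = np.isfinite(l1) & np.isfinite(l2) & np.isfinite(l3)
    tol = 1e-9
    if np.any((l1[valid] < l2[valid] - tol) | (l2[valid] < l3[valid] - tol)):
        raise ValueError("principal stretches must be sorted descending (l1 >= l2 >= l3)")
    if np.any(l3[valid] <= 0):
        raise ValueError("l3 must be positive")


def adi(l1, l2, l3):
    """Anisotropic deformation index; 0 iff the deformation is isotropic,
    scale-free in the stretches."""
    _check_sorted(l1, l2, l3)
    l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
    out = np.sqrt(((l1 - l2) / l2) ** 2 + ((l2 - l3) / l3) ** 2)
    return out if out.ndim else float(out)


def sri(l1, l2, l3):
    """Slab-rod index in [0, 1]: 0 for slab-like (l1 = l2 > l3), 1 for
    rod-like (l1 > l2 = l3); isotropic deformation maps to 0 by the
    atan2(0, 0) = 0 convention."""
    _check_sorted(l1, l2, l3)
    l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
    out = (2.0 / np.pi) * np.arctan2((l1 - l2) / l2, (l2 - l3) / l3)
    return out if out.ndim else float(out)


@dataclass
class DeformationTensors:
    """Per-voxel deformation gradient and derived scalar fields."""

    F: np.ndarray  # (..., 3, 3)
    J: np.ndarray
    stretches: np.ndarray  # (..., 3) descending
    ADI: np.ndarray
    SRI: np.ndarray


def compute_tensors(field: DisplacementField) -> DeformationTensors:
    """Full tensor pipeline: F, J, principal stretches, ADI, SRI per voxel."""
    F = deformation_gradient(field)
    J = jacobian(F)
    lam = principal_stretches(F)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.sqrt(((l1 - l2) / l2) ** 2 + ((l2 - l3) / l3) ** 2)
        S = (2.0 / np.pi) * np.arctan2((l1 - l2) / l2, (l2 - l3) / l3)
    return DeformationTensors(F=F, J=J, stretches=lam, ADI=A, SRI=S)


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return (np.nan, np.nan, np.nan)
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return float(q25), float(med), float(q75)


@dataclass
class RegionalDeformationSummary:
    """Median/IQR of J, ADI, SRI per region plus apex-to-base slice profiles."""

    per_region: pd.DataFrame  # rows: region; cols: metric_q25/median/q75
    depth_profile: pd.DataFrame  # rows: (region, depth_fraction); cols: metric medians
    metadata: dict


def regional_summary(
    tensors: DeformationTensors,
    lobe_mask: LobeMask,
    depth_fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    *,
    axis: int = 2,
    apex: str = "high",
) -> RegionalDeformationSummary:
    """Summarize J/ADI/SRI over the standard regions (WL, RL, LL, five lobes)
    and along the apex-to-base axis at the given depth fractions (0 = apex).

    ``apex='high'`` means the apical (superior) end sits at the largest index
    of ``axis`` (feet-first array ordering); flagged regions with no voxels
    yield NaN rows.
    """
    metrics = {"J": tensors.J, "ADI": tensors.ADI, "SRI": tensors.SRI}
    rows = {}
    empty = []
    for region in REGIONS:
        sel = lobe_mask.region_mask(region)
        if not sel.any():
            empty.append(region)
            rows[region] = {f"{m}_{q}": np.nan for m in metrics for q in ("q25", "median", "q75")}
            continue
        row = {}
        for name, vals in metrics.items():
            q25, med, q75 = _quartiles(vals[sel])
            row[f"{name}_q25"] = q25
            row[f"{name}_median"] = med
            row[f"{name}_q75"] = q75
        rows[region] = row
    per_region = pd.DataFrame(rows).T

    # apex-to-base slice profile over the in-mask extent
    prof_rows = []
    for region in REGIONS:
        sel = lobe_mask.region_mask(region)
        if not sel.any():
            continue
        occupied = np.any(sel, axis=tuple(i for i in range(3) if i != axis))
        lo = int(np.argmax(occupied))
        hi = len(occupied) - 1 - int(np.argmax(occupied[::-1]))
        for f in depth_fractions:
            if apex == "high":
                k = int(round(hi - f * (hi - lo)))
            elif apex == "low":
                k = int(round(lo + f * (hi - lo)))
            else:
                raise ValueError("apex must be 'high' or 'low'")
            slicer = [slice(None)] * 3
            slicer[axis] = k
            sl = tuple(slicer)
            sel_sl = sel[sl]
            row = {"region": region, "depth_fraction": f}
            for name, vals in metrics.items():
                v = vals[sl][sel_sl]
                v = v[np.isfinite(v)]
                row[name] = float(np.median(v)) if v.size else np.nan
            prof_rows.append(row)
    depth_profile = pd.DataFrame(prof_rows).set_index(["region", "depth_fraction"])

    meta = dict(METRIC_PROVENANCE)
    meta["apex_convention"] = f"apex at {apex} index of axis {axis}"
    if empty:
        meta["empty_regions"] = empty
    return RegionalDeformationSummary(
        per_region=per_region, depth_profile=depth_profile, metadata=meta
    )
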