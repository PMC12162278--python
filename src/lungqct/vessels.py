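"""Cumulative blood-vessel volume profiles.

BVk (k = 1..20) is the total volume (cc) of vessel voxels whose local
cross-sectional area is strictly less than k mm^2; TBV is the volume of all
vessel voxels. The profile is cumulative by construction:
0 <= BV1 <= ... <= BV20 <= TBV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .grid import LobeMask, REGIONS, VesselCSAMap

__all__ = ["BVProfile", "bv_profile", "bv_profiles_all_regions", "csa_from_radius", "profiles_to_frame"]

N_BINS = 20


@dataclass
class BVProfile:
    """BV1..BV20 and TBV in cc for one region."""

    bv: np.ndarray  # shape (20,), bv[k-1] = BVk
    tbv: float
    region: str = "WL"

    def __post_init__(self) -> None:
        self.bv = np.asarray(self.bv, dtype=float)
        if self.bv.shape != (N_BINS,):
            raise ValueError(f"profile must have {N_BINS} entries")
        if np.any(np.diff(self.bv) < -1e-12) or self.bv[-1] > self.tbv + 1e-12:
            raise ValueError("BV profile must be non-decreasing with BV20 <= TBV")


def bv_profile(
    csa_map: VesselCSAMap,
    region_mask: Optional[np.ndarray] = None,
    region: str = "WL",
) -> BVProfile:
    """Profile over the whole map or a boolean region mask."""
    areas = csa_map.data
    vessel = csa_map.vessel_mask
    if region_mask is not None:
        if region_mask.shape != areas.shape:
            raise ValueError("region mask shape does not match vessel map")
        vessel = vessel & region_mask
    vv_cc = csa_map.grid.voxel_volume_mm3 / 1000.0
    a = areas[vessel]
    bv = np.array([float((a < k).sum()) * vv_cc for k in range(1, N_BINS + 1)])
    return BVProfile(bv=bv, tbv=float(a.size) * vv_cc, region=region)


def bv_profiles_all_regions(
    csa_map: VesselCSAMap, lobe_mask: LobeMask
) -> dict[str, BVProfile]:
    """One profile per region in {WL, RL, LL, LUL, LLL, RUL, RML, RLL}.

    Note the whole-lung profile counts in-lung vessel voxels only, so
    WL = RL + LL element-wise (additivity over disjoint regions).
    """
    if lobe_mask.shape != csa_map.data.shape:
        raise ValueError("lobe mask not aligned with vessel map")
    return {
        region: bv_profile(csa_map, lobe_mask.region_mask(region), region)
        for region in REGIONS
    }


def csa_from_radius(radius_map: np.ndarray) -> np.ndarray:
    """Helper: local cross-sectional area pi r^2 from a centerline-radius
    field (mm); for use when upstream segmentation exports radii rather than
    areas."""
    r = np.asarray(radius_map, dtype=float)
    if np.any(r < 0):
        raise ValueError("radii must be non-negative")
    return math.pi * r**2


def profiles_to_frame(profiles: dict[str, BVProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame: rows BV1..BV20 + TBV, one column per region."""
    index = [f"BV{k}" for k in range(1, N_BINS + 1)] + ["TBV"]
    data = {
        region: list(p.bv) + [p.tbv] for region, p in profiles.items()
    }
    return pd.DataFrame(data, index=index)
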