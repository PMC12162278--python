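"""HU-based parenchymal classification.

Lung voxels are classified by Hounsfield-unit thresholds into five primary
states that tile integer HU up to 60 without gap or overlap —

=============  =================
Emph           HU <= -951  (strictly below -950)
Norm           -950 .. -701
GGO            -700 .. -501
Semiconso      -500 .. -201
Conso          -200 .. 60
=============  =================

— plus fibrosis (Fibr, -500 .. 0), which by definition overlaps the
semi-consolidation and consolidation ranges and is therefore reported as an
overlapping mask, never subtracted. In-mask voxels above 60 HU form an
explicit "Dense" remainder (no class is defined above 60). All endpoints are
inclusive on integer HU.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .grid import HUVolume, Lobe, LobeMask

__all__ = [
    "PRIMARY_CLASSES",
    "FIBR_RANGE",
    "classify_hu",
    "class_fractions",
    "hu_histogram",
]

#: Primary classes as inclusive integer-HU intervals (lo, hi); Emph is
#: open-ended below.
PRIMARY_CLASSES: dict[str, tuple[int, int]] = {
    "Emph": (-(10**9), -951),
    "Norm": (-950, -701),
    "GGO": (-700, -501),
    "Semiconso": (-500, -201),
    "Conso": (-200, 60),
}

FIBR_RANGE: tuple[int, int] = (-500, 0)

CLASS_ORDER = ["Emph", "Norm", "GGO", "Semiconso", "Conso", "Fibr", "Dense"]


def classify_hu(vol: HUVolume, mask: LobeMask) -> dict[str, np.ndarray]:
    """Per-class boolean maps over in-mask voxels.

    Each in-mask voxel lands in exactly one primary class (or the Dense
    above-60 remainder) and additionally in Fibr when -500 <= HU <= 0.
    """
    if vol.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {vol.shape} vs mask {mask.shape}")
    lung = mask.in_lung
    hu = vol.data
    maps: dict[str, np.ndarray] = {}
    for name, (lo, hi) in PRIMARY_CLASSES.items():
        maps[name] = lung & (hu >= lo) & (hu <= hi)
    maps["Fibr"] = lung & (hu >= FIBR_RANGE[0]) & (hu <= FIBR_RANGE[1])
    maps["Dense"] = lung & (hu > 60)
    return maps


def class_fractions(
    maps: dict[str, np.ndarray],
    mask: LobeMask,
    *,
    denominator: str = "in_mask",
    vol: Optional[HUVolume] = None,
) -> pd.DataFrame:
    """Per-lobe and Total class percentages (rows: five lobes + Total).

    ``denominator='in_mask'`` divides by all in-mask voxels of the region;
    ``'aerated'`` divides by in-mask voxels with HU in [-1000, 0] (requires
    ``vol``). Empty lobes yield NaN rows (flagged in ``attrs``).
    """
    if denominator == "aerated":
        if vol is None:
            raise ValueError("denominator='aerated' requires the HU volume")
        aer = (vol.data >= -1000) & (vol.data <= 0)
    elif denominator != "in_mask":
        raise ValueError(f"unknown denominator {denominator!r}")

    regions = [l.name for l in Lobe] + ["Total"]
    rows = {}
    empty = []
    for region in regions:
        sel = mask.in_lung if region == "Total" else (mask.data == int(Lobe[region]))
        if denominator == "aerated":
            denom = int((sel & aer).sum())
        else:
            denom = int(sel.sum())
        if denom == 0:
            empty.append(region)
            rows[region] = {c: np.nan for c in CLASS_ORDER}
            continue
        # 100 * (count/denom): same expression order as generator-realized
        # fractions, so count-exact phantoms are recovered bit-identically
        rows[region] = {
            c: 100.0 * (int((maps[c] & sel).sum()) / denom) for c in CLASS_ORDER
        }
    out = pd.DataFrame(rows).T[CLASS_ORDER]
    out.attrs["denominator"] = denominator
    out.attrs["empty_regions"] = empty
    return out


def hu_histogram(
    vol: HUVolume,
    mask: LobeMask,
    hu_range: tuple[int, int] = (-1000, 0),
) -> tuple[np.ndarray, np.ndarray, int]:
    """Voxel counts in 1-HU-wide bins over the closed ``hu_range`` (default
    -1000..0, aerated lung tissue). Returns (hu values, counts, total)."""
    if vol.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {vol.shape} vs mask {mask.shape}")
    lo, hi = hu_range
    hu = vol.data[mask.in_lung]
    hu = hu[(hu >= lo) & (hu <= hi)]
    values = np.arange(lo, hi + 1)
    counts = np.bincount(hu - lo, minlength=hi - lo + 1)
    return values, counts, int(counts.sum())
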