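"""Image-grid containers shared across the package.

All volumes live on a regular grid with 0-based voxel indices; the
index -> world map is ``world = spacing * index + origin`` (mm), applied
per axis. Arrays are indexed ``(i, j, k)`` matching world axes ``(x, y, z)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

HU_MIN = -1024
HU_MAX = 3071


class Lobe(IntEnum):
    """Five-lobe labelling used by lobe masks (0 is background)."""

    LUL = 1
    LLL = 2
    RUL = 3
    RML = 4
    RLL = 5


#: Region names -> lobes they comprise. WL = whole lung, RL/LL = right/left lung.
REGIONS: dict[str, tuple[Lobe, ...]] = {
    "WL": (Lobe.LUL, Lobe.LLL, Lobe.RUL, Lobe.RML, Lobe.RLL),
    "RL": (Lobe.RUL, Lobe.RML, Lobe.RLL),
    "LL": (Lobe.LUL, Lobe.LLL),
    "LUL": (Lobe.LUL,),
    "LLL": (Lobe.LLL,),
    "RUL": (Lobe.RUL,),
    "RML": (Lobe.RML,),
    "RLL": (Lobe.RLL,),
}


def _as_triple(value) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class Grid:
    """Geometry of a regular 3-D grid: voxel spacing and origin in mm."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        return np.asarray(index, dtype=float) * np.array(self.spacing) + np.array(self.origin)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        return (np.asarray(world, dtype=float) - np.array(self.origin)) / np.array(self.spacing)

    def same_geometry(self, other: "Grid", shape_a=None, shape_b=None) -> bool:
        ok = np.allclose(self.spacing, other.spacing) and np.allclose(self.origin, other.origin)
        if shape_a is not None and shape_b is not None:
            ok = ok and tuple(shape_a) == tuple(shape_b)
        return ok


@dataclass
class HUVolume:
    """Calibrated CT volume: integer Hounsfield units on a regular grid."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("HUVolume data must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError("HU values must be integers (CT convention)")
        if self.data.size and (self.data.min() < HU_MIN or self.data.max() > HU_MAX):
            raise ValueError(f"HU values outside scanner range [{HU_MIN}, {HU_MAX}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LobeMask:
    """Label volume over {background} | five lobes, aligned with a companion HUVolume."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LobeMask data must be 3-D")
        valid = {0} | {int(l) for l in Lobe}
        present = set(np.unique(self.data).tolist())
        if not present <= valid:
            raise ValueError(f"unknown lobe labels {sorted(present - valid)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def region_mask(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise KeyError(f"unknown region {region!r}; expected one of {sorted(REGIONS)}")
        return np.isin(self.data, [int(l) for l in REGIONS[region]])

    @property
    def in_lung(self) -> np.ndarray:
        return self.data > 0


@dataclass
class VesselCSAMap:
    """Per-voxel vessel map; vessel voxels carry their local cross-sectional area (mm^2)."""

    data: np.ndarray  # 0 background, >0 local CSA in mm^2
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("VesselCSAMap data must be 3-D")
        if self.data.size and self.data.min() < 0:
            raise ValueError("cross-sectional areas must be non-negative")

    @property
    def vessel_mask(self) -> np.ndarray:
        return self.data > 0


@dataclass
class DisplacementField:
    """3-D displacement vectors u(x) in mm, fixed-image frame, shape (nx, ny, nz, 3)."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError("DisplacementField data must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]
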