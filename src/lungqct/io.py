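"""File formats: NIfTI/MetaImage volumes via SimpleITK, skeleton JSON,
cohort CSV.

Arrays are held in (x, y, z) index order with world = spacing*index + origin;
SimpleITK stores (z, y, x), so reads/writes transpose. Vector displacement
fields round-trip as vector images. Floating-point CSV output is written at
6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .airway import AirwaySkeleton, Branch
from .grid import DisplacementField, Grid, HUVolume, LobeMask, VesselCSAMap

__all__ = [
    "write_volume",
    "read_hu_volume",
    "read_lobe_mask",
    "read_csa_map",
    "write_displacement_field",
    "read_displacement_field",
    "write_skeleton_json",
    "read_skeleton_json",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_csv",
]

CSV_FLOAT_FORMAT = "%.6g"

VolumeLike = Union[HUVolume, LobeMask, VesselCSAMap]


def _to_image(data: np.ndarray, grid: Grid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    return img


def _from_image(img: sitk.Image) -> tuple[np.ndarray, Grid]:
    data = sitk.GetArrayFromImage(img).T
    return data, Grid(spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def write_volume(vol: VolumeLike, path: str | Path) -> None:
    """Write any scalar volume container as .nii.gz or .mha."""
    sitk.WriteImage(_to_image(vol.data, vol.grid), str(path))


def read_hu_volume(path: str | Path) -> HUVolume:
    data, grid = _from_image(sitk.ReadImage(str(path)))
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: HU volume has non-integer values")
        data = np.round(data).astype(np.int16)
    return HUVolume(data=data, grid=grid)


def read_lobe_mask(path: str | Path) -> LobeMask:
    data, grid = _from_image(sitk.ReadImage(str(path)))
    return LobeMask(data=data.astype(np.uint8), grid=grid)


def read_csa_map(path: str | Path) -> VesselCSAMap:
    data, grid = _from_image(sitk.ReadImage(str(path)))
    return VesselCSAMap(data=data, grid=grid)


def write_displacement_field(field: DisplacementField, path: str | Path) -> None:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(field.data.transpose(2, 1, 0, 3)), isVector=True
    )
    img.SetSpacing(field.grid.spacing)
    img.SetOrigin(field.grid.origin)
    sitk.WriteImage(img, str(path))


def read_displacement_field(path: str | Path) -> DisplacementField:
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a 3-component vector field")
    return DisplacementField(
        data=data.transpose(2, 1, 0, 3),
        grid=Grid(spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin())),
    )


def write_skeleton_json(skel: AirwaySkeleton, path: str | Path) -> None:
    payload = {
        "points": skel.points.tolist(),
        "edges": [list(e) for e in skel.edges],
        "branches": [
            {"label": b.label, "point_ids": list(b.point_ids)} for b in skel.branches
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_skeleton_json(path: str | Path) -> AirwaySkeleton:
    payload = json.loads(Path(path).read_text())
    return AirwaySkeleton(
        points=np.asarray(payload["points"], dtype=float),
        edges=[tuple(e) for e in payload["edges"]],
        branches=[
            Branch(label=b["label"], point_ids=list(b["point_ids"]))
            for b in payload["branches"]
        ],
    )


COHORT_COLUMNS = ["subject_id", "metric", "baseline", "followup", "interval_days"]


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns {sorted(missing)}")
    return df


def write_csv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, index=index, float_format=CSV_FLOAT_FORMAT)
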