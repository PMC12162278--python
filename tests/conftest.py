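import math

import numpy as np
import pytest

from lungqct import AirwaySkeleton, Grid, TubePhantomSpec, make_tube_phantom, tube_masks
from lungqct.airway import Branch


@pytest.fixture(scope="session")
def fine_tube():
    """Circular tube r=5 mm, wall 1 mm, 0.25 mm spacing: phantom volume,
    masks, skeleton and analytic ground truth."""
    spec = TubePhantomSpec(inner_radius=5.0, wall_thickness_true=1.0, voxel_spacing=0.25)
    vol, skel, gt = make_tube_phantom(spec)
    lumen, wall = tube_masks(vol, spec)
    return {"spec": spec, "vol": vol, "skel": skel, "gt": gt, "lumen": lumen, "wall": wall}


def voxelize_skeleton_tubes(skel: AirwaySkeleton, radii: dict, wall: float,
                            spacing: float, margin: float = 3.0):
    """Voxelize a polyline skeleton into lumen/wall masks: a voxel is lumen
    if within ``radii[label]`` of any segment of that branch, wall if within
    radius + wall. Returns (lumen, wall_mask, grid)."""
    lo = skel.points.min(axis=0) - margin - max(radii.values()) - wall
    hi = skel.points.max(axis=0) + margin + max(radii.values()) + wall
    shape = tuple(int(math.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    grid = Grid(spacing=(spacing,) * 3, origin=tuple(lo))
    idx = np.indices(shape, dtype=float)
    world = np.stack([idx[i] * spacing + lo[i] for i in range(3)], axis=-1)
    pts_flat = world.reshape(-1, 3)
    lumen = np.zeros(len(pts_flat), dtype=bool)
    total = np.zeros(len(pts_flat), dtype=bool)
    for b in skel.branches:
        r = radii[b.label]
        seg_pts = skel.points[b.point_ids]
        for a, c in zip(seg_pts[:-1], seg_pts[1:]):
            d = c - a
            L2 = float(d @ d)
            t = np.clip((pts_flat - a) @ d / L2, 0, 1) if L2 > 0 else 0
            nearest = a + t[:, None] * d
            dist = np.linalg.norm(pts_flat - nearest, axis=1)
            lumen |= dist <= r
            total |= dist <= r + wall
    lumen = lumen.reshape(shape)
    wall_mask = total.reshape(shape) & ~lumen
    return lumen, wall_mask, grid
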