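"""Airway morphometry: scalar metrics, sub-pixel cross-section measurement,
and the branch table."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from lungqct import (
    TubePhantomSpec,
    bifurcation_angle,
    circularity,
    hydraulic_diameter,
    make_bifurcation_skeleton,
    make_tube_phantom,
    measure_cross_section,
    tube_masks,
)
from lungqct.airway import branch_table, records_to_frame

from conftest import voxelize_skeleton_tubes


def ellipse_perimeter_quad(a: float, b: float) -> float:
    """Independent oracle: arclength integral by numerical quadrature."""
    f = lambda t: math.hypot(a * math.sin(t), b * math.cos(t))
    val, _ = quad(f, 0, 2 * math.pi)
    return val


class TestBifurcationAngle:
    @pytest.mark.parametrize(
        "d1,d2,expected",
        [
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (1, 1, 0), 45.0),
            ((1, 0, 0), (-1, 0, 0), 180.0),
            ((2, 0, 0), (2, 0, 0), 0.0),
        ],
    )
    def test_examples(self, d1, d2, expected):
        assert bifurcation_angle(d1, d2) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            bifurcation_angle((0, 0, 0), (1, 0, 0))

    unit = st.tuples(*[st.floats(-1, 1) for _ in range(3)]).filter(
        lambda v: np.linalg.norm(v) > 1e-3
    )

    @settings(derandomize=True, max_examples=50)
    @given(d1=unit, d2=unit, seed=st.integers(0, 10**6))
    def test_symmetry_and_rotation_invariance(self, d1, d2, seed):
        """theta(d1,d2) = theta(d2,d1), and a common proper rotation leaves
        the angle unchanged."""
        assert bifurcation_angle(d1, d2) == pytest.approx(
            bifurcation_angle(d2, d1), abs=1e-9
        )
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        # arccos is ill-conditioned at 0/180 deg, so the tight tolerance
        # applies away from near-parallel pairs
        cos = abs(np.dot(d1, d2) / (np.linalg.norm(d1) * np.linalg.norm(d2)))
        tol = 1e-9 if cos < 0.999 else 1e-5
        assert bifurcation_angle(q @ np.asarray(d1), q @ np.asarray(d2)) == pytest.approx(
            bifurcation_angle(d1, d2), abs=tol
        )


class TestScalarMetrics:
    @pytest.mark.parametrize(
        "LA,Pe,expected",
        [
            (math.pi * 25, 2 * math.pi * 5, 10.0),  # circle r=5 -> 2r
            (4.0, 8.0, 2.0),  # square side 2 -> a
            (50.0, 30.0, 50 * 4 / 30),
        ],
    )
    def test_hydraulic_diameter(self, LA, Pe, expected):
        assert hydraulic_diameter(LA, Pe) == pytest.approx(expected)

    def test_hydraulic_diameter_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            hydraulic_diameter(0.0, 10.0)

    def test_circularity_circle_is_one(self):
        assert circularity(10.0, 10 * math.pi) == pytest.approx(1.0, abs=1e-15)

    def test_circularity_ellipse_oracle(self):
        """Ellipse a=2, b=1 with D_inner the equivalent-area diameter;
        perimeter from independent quadrature."""
        LA = math.pi * 2 * 1
        d_inner = 2 * math.sqrt(LA / math.pi)
        pe = ellipse_perimeter_quad(2.0, 1.0)
        assert circularity(d_inner, pe) == pytest.approx(0.9171, abs=5e-4)

    def test_circularity_thin_slit_tends_to_zero(self):
        assert circularity(1.0, 1e6) < 1e-5


class TestMeasureCrossSection:
    def test_tube_recovers_analytic_circle(self, fine_tube):
        m = measure_cross_section(
            fine_tube["lumen"], fine_tube["wall"], fine_tube["vol"].grid,
            fine_tube["skel"], "Trachea",
        )
        gt = fine_tube["gt"]
        assert m.LA == pytest.approx(gt.LA, rel=0.02)
        assert m.P_e == pytest.approx(gt.P_e, rel=0.02)
        assert m.WT == pytest.approx(2.0, rel=0.10)  # diameter-difference convention

    def test_wall_thickness_radial_convention(self, fine_tube):
        m = measure_cross_section(
            fine_tube["lumen"], fine_tube["wall"], fine_tube["vol"].grid,
            fine_tube["skel"], "Trachea", wt_convention="radial",
        )
        assert m.WT == pytest.approx(1.0, rel=0.10)

    def test_elliptical_tube_circularity(self):
        """a = 2b lumen: Cr should match the quadrature oracle within 0.02."""
        spec = TubePhantomSpec(inner_radius=5.0, wall_thickness_true=0.0,
                               ellipse_ratio=2.0, voxel_spacing=0.25)
        vol, skel, gt = make_tube_phantom(spec)
        lumen, _ = tube_masks(vol, spec)
        m = measure_cross_section(lumen, None, vol.grid, skel, "Trachea")
        a, b = spec.semi_axes
        assert a == pytest.approx(2 * b)
        cr_true = math.pi * 2 * math.sqrt(a * b) / ellipse_perimeter_quad(a, b)
        assert cr_true == pytest.approx(0.9171, abs=1e-3)
        assert circularity(m.D_inner, m.P_e) == pytest.approx(cr_true, abs=0.02)

    def test_isoperimetric_invariant(self, fine_tube):
        """P_e >= 2 sqrt(pi LA) after sub-pixel perimeter estimation, i.e.
        Cr <= 1 (+ discretization slack)."""
        for station in (0.3, 0.5, 0.7):
            m = measure_cross_section(
                fine_tube["lumen"], fine_tube["wall"], fine_tube["vol"].grid,
                fine_tube["skel"], "Trachea", station=station,
            )
            assert m.P_e >= 2 * math.sqrt(math.pi * m.LA) * (1 - 1e-9)
            assert circularity(m.D_inner, m.P_e) <= 1.02

    def test_plane_missing_lumen_errors_with_context(self, fine_tube):
        """A lumen displaced away from the centerline plane raises an error
        identifying the branch and station."""
        shifted = np.roll(fine_tube["lumen"], fine_tube["lumen"].shape[0] // 2, axis=0)
        with pytest.raises(ValueError, match="Trachea"):
            measure_cross_section(
                shifted, None, fine_tube["vol"].grid, fine_tube["skel"], "Trachea",
                plane_halfwidth_mm=8.0,
            )


class TestBranchTable:
    def test_bifurcation_phantom_three_records_with_theta(self):
        skel = make_bifurcation_skeleton(
            (0, 0, 1), ((1, 0, 1), (-1, 0, 1)), branch_length=24.0
        )
        lumen, wall, grid = voxelize_skeleton_tubes(
            skel, {"Trachea": 4.0, "LMB": 3.0, "RMB": 3.0}, wall=1.0, spacing=0.5
        )
        records = branch_table(skel, lumen, wall, grid)
        by_label = {r.label: r for r in records}
        assert set(by_label) == {"Trachea", "LMB", "RMB"}
        assert by_label["Trachea"].theta == pytest.approx(90.0, abs=1.0)
        assert by_label["LMB"].theta is None
        assert by_label["Trachea"].Dh == pytest.approx(8.0, rel=0.05)

    def test_subgroup_is_mean_of_members(self):
        """Two RML segmental tubes with D_h 4 and 6 -> subgroup D_h = 5."""
        from lungqct.airway import AirwaySkeleton, Branch

        pts = np.array(
            [[0, 0, 0], [0, 0, 20], [15, 0, 0], [15, 0, 20]], dtype=float
        )
        skel = AirwaySkeleton(
            points=pts,
            edges=[],
            branches=[Branch("RB4", [0, 1]), Branch("RB5", [2, 3])],
        )
        lumen, wall, grid = voxelize_skeleton_tubes(
            skel, {"RB4": 2.0, "RB5": 3.0}, wall=0.5, spacing=0.25
        )
        records = branch_table(skel, lumen, wall, grid)
        by_label = {r.label: r for r in records}
        assert by_label["RML"].Dh == pytest.approx(
            (by_label["RB4"].Dh + by_label["RB5"].Dh) / 2
        )
        assert by_label["RB4"].Dh == pytest.approx(4.0, rel=0.03)
        assert by_label["RB5"].Dh == pytest.approx(6.0, rel=0.03)

    def test_missing_wall_mask_marks_wt_absent(self, fine_tube):
        records = branch_table(
            fine_tube["skel"], fine_tube["lumen"], None, fine_tube["vol"].grid
        )
        rec = next(r for r in records if r.label == "Trachea")
        assert math.isnan(rec.WT)
        assert rec.Dh == pytest.approx(10.0, rel=0.02)

    def test_unknown_label_rejected(self, fine_tube):
        skel = fine_tube["skel"]
        bad = type(skel)(
            points=skel.points,
            edges=skel.edges,
            branches=[type(skel.branches[0])("XB9", skel.branches[0].point_ids)],
        )
        with pytest.raises(ValueError, match="XB9"):
            branch_table(bad, fine_tube["lumen"], None, fine_tube["vol"].grid)

    def test_records_frame_columns(self, fine_tube):
        df = records_to_frame(
            branch_table(fine_tube["skel"], fine_tube["lumen"], fine_tube["wall"],
                         fine_tube["vol"].grid)
        )
        assert list(df.columns) == [
            "label", "theta_deg", "Dh_mm", "WT_mm", "Cr", "LA_mm2", "Pe_mm",
        ]
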