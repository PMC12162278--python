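"""Deformation tensors: gradients, Jacobian, principal stretches, ADI/SRI
and their invariances."""

import math

import numpy as np
import pytest

from lungqct import (
    AffineFieldSpec,
    DisplacementField,
    Grid,
    Lobe,
    LobeMask,
    adi,
    compute_tensors,
    deformation_gradient,
    jacobian,
    make_affine_displacement,
    principal_stretches,
    regional_summary,
    sri,
)


def _field(u, spacing=(1, 1, 1)):
    return DisplacementField(data=u, grid=Grid(spacing=spacing))


class TestGradient:
    def test_zero_displacement_gives_identity(self):
        F = deformation_gradient(_field(np.zeros((5, 5, 5, 3))))
        assert np.allclose(F, np.eye(3))

    def test_affine_field_exact_interior(self):
        """Central differences are exact on linear fields: interior F = A."""
        A = np.array([[1.1, 0.02, 0.0], [0.01, 0.95, 0.03], [0.0, 0.0, 1.05]])
        fld, _ = make_affine_displacement(
            AffineFieldSpec(A=A, grid_shape=(8, 8, 8), voxel_spacing=(1.0, 0.7, 1.3))
        )
        F = deformation_gradient(fld)
        assert np.allclose(F[1:-1, 1:-1, 1:-1], A, atol=1e-10)

    def test_uniaxial_stretch(self):
        shape = (6, 6, 6)
        x = np.arange(shape[0])[:, None, None, None] * 1.0
        u = np.zeros(shape + (3,))
        u[..., 0:1] = 0.1 * x
        F = deformation_gradient(_field(u))
        assert np.allclose(F[..., 0, 0], 1.1)
        assert np.allclose(F[..., 0, 1], 0.0)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError, match="3 voxels"):
            deformation_gradient(_field(np.zeros((2, 5, 5, 3))))


class TestJacobianAndStretches:
    @pytest.mark.parametrize(
        "F,expected",
        [
            (np.eye(3), 1.0),
            (1.1 * np.eye(3), 1.331),
            (np.diag([1.2, 1.0, 0.8]), 0.96),
        ],
    )
    def test_jacobian(self, F, expected):
        assert jacobian(F) == pytest.approx(expected)

    def test_diagonal_stretches(self):
        lam = principal_stretches(np.diag([1.2, 1.1, 1.0]))
        assert np.allclose(lam, [1.2, 1.1, 1.0])

    def test_rotation_is_isometric(self):
        th = 0.4
        R = np.array(
            [[math.cos(th), -math.sin(th), 0], [math.sin(th), math.cos(th), 0], [0, 0, 1]]
        )
        assert np.allclose(principal_stretches(R), 1.0)

    def test_simple_shear_closed_form(self):
        """F = I + g e1 e2^T: closed-form eigenvalues of C give
        l1*l3 = 1 and l2 = 1."""
        g = 0.1
        F = np.eye(3)
        F[0, 1] = g
        l1, l2, l3 = principal_stretches(F)
        assert l2 == pytest.approx(1.0, abs=1e-12)
        assert l1 * l3 == pytest.approx(1.0, abs=1e-12)
        lam1 = math.sqrt(1 + g**2 / 2 + g * math.sqrt(1 + g**2 / 4))
        assert l1 == pytest.approx(lam1, abs=1e-12)

    def test_det_identity_property(self):
        """J = l1 l2 l3 within 1e-6 relative on 1e4 random well-conditioned
        deformation gradients."""
        rng = np.random.default_rng(42)
        F = np.eye(3) + 0.2 * rng.standard_normal((10_000, 3, 3))
        J = jacobian(F)
        keep = J > 0.1
        lam = principal_stretches(F[keep])
        assert np.allclose(lam.prod(axis=-1), J[keep], rtol=1e-6)


class TestADISRI:
    def test_isotropic_adi_zero(self):
        assert adi(1.3, 1.3, 1.3) == 0.0
        assert adi(0.7, 0.7, 0.7) == 0.0

    def test_hand_value(self):
        assert adi(1.2, 1.1, 1.0) == pytest.approx(
            math.sqrt((0.1 / 1.1) ** 2 + (0.1 / 1.0) ** 2), abs=1e-12
        )
        assert adi(1.2, 1.1, 1.0) == pytest.approx(0.13514, abs=1e-4)

    def test_scale_free(self):
        for c in (0.5, 1.0, 3.0):
            assert adi(2 * c, c, c) == pytest.approx(adi(2, 1, 1), abs=1e-12)

    def test_sri_polarity(self):
        assert sri(1.4, 1.4, 0.9) == 0.0  # slab-like: l1 = l2 > l3
        assert sri(1.4, 0.9, 0.9) == 1.0  # rod-like: l1 > l2 = l3
        assert sri(1.2, 1.1, 1.0) == pytest.approx(
            (2 / math.pi) * math.atan2(0.1 / 1.1, 0.1 / 1.0), abs=1e-12
        )
        assert sri(1.2, 1.1, 1.0) == pytest.approx(0.4697, abs=1e-4)

    def test_sri_bounded(self):
        rng = np.random.default_rng(3)
        lam = np.sort(rng.uniform(0.5, 1.5, size=(500, 3)), axis=1)[:, ::-1]
        s = sri(lam[:, 0], lam[:, 1], lam[:, 2])
        assert np.all((s >= 0) & (s <= 1))

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            adi(1.0, 1.1, 1.2)
        with pytest.raises(ValueError, match="sorted"):
            sri(1.0, 1.1, 1.2)

    def test_rotation_invariance(self):
        """Pre/post-multiplying F by rotations leaves J, ADI, SRI unchanged."""
        rng = np.random.default_rng(9)
        F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
        q1, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        q2, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        for q in (q1, q2):
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
        for G in (q1 @ F, F @ q2, q1 @ F @ q2):
            for X, Y in [(F, G)]:
                lx = principal_stretches(X)
                ly = principal_stretches(Y)
                assert abs(jacobian(X)) == pytest.approx(abs(jacobian(Y)), abs=1e-9)
                assert adi(*lx) == pytest.approx(adi(*ly), abs=1e-9)
                assert sri(*lx) == pytest.approx(sri(*ly), abs=1e-9)


class TestRegionalSummary:
    def _lobes(self, shape):
        labels = np.zeros(shape, dtype=np.uint8)
        half = shape[0] // 2
        labels[:half, :, shape[2] // 2 :] = Lobe.LUL
        labels[:half, :, : shape[2] // 2] = Lobe.LLL
        labels[half:, :, 2 * shape[2] // 3 :] = Lobe.RUL
        labels[half:, :, shape[2] // 3 : 2 * shape[2] // 3] = Lobe.RML
        labels[half:, :, : shape[2] // 3] = Lobe.RLL
        return labels

    def test_uniform_affine_medians_and_zero_iqr(self):
        A = np.diag([1.1, 1.0, 0.95])
        fld, closed = make_affine_displacement(AffineFieldSpec(A=A, grid_shape=(12, 12, 12)))
        t = compute_tensors(fld)
        mask = LobeMask(data=self._lobes((12, 12, 12)), grid=fld.grid)
        summ = regional_summary(t, mask)
        for region in ("WL", "LUL", "RLL"):
            assert summ.per_region.loc[region, "J_median"] == pytest.approx(closed["J"], abs=1e-10)
            assert summ.per_region.loc[region, "ADI_median"] == pytest.approx(closed["ADI"], abs=1e-10)
            iqr = summ.per_region.loc[region, "J_q75"] - summ.per_region.loc[region, "J_q25"]
            assert iqr == pytest.approx(0.0, abs=1e-10)

    def test_basal_contraction_gradient(self):
        """A field contracting only the basal half yields smaller J median
        near the base (depth 0.8) than near the apex (depth 0.2)."""
        shape = (10, 10, 20)
        u = np.zeros(shape + (3,))
        z = np.arange(shape[2])
        # basal half (low z with apex='high'): contract x by 10%
        x = np.arange(shape[0])[:, None, None] * 1.0
        u[..., 0] = np.where(z[None, None, :] < shape[2] // 2, -0.1 * x, 0.0)
        fld = _field(u)
        t = compute_tensors(fld)
        mask = LobeMask(data=self._lobes(shape), grid=fld.grid)
        summ = regional_summary(t, mask)
        prof = summ.depth_profile.loc["WL"]
        assert prof.loc[0.8, "J"] < prof.loc[0.2, "J"]

    def test_two_block_field_recovers_blockwise_closed_forms(self):
        """Different affine blocks in left and right halves: lobe summaries
        recover each block's closed form."""
        shape = (16, 8, 8)
        A_left = np.diag([1.08, 1.0, 1.0])
        A_right = np.diag([0.94, 0.94, 0.94])
        _, cf_left = make_affine_displacement(AffineFieldSpec(A=A_left, grid_shape=(4, 4, 4)))
        _, cf_right = make_affine_displacement(AffineFieldSpec(A=A_right, grid_shape=(4, 4, 4)))
        idx = np.indices(shape, dtype=float)
        world = np.stack(idx, axis=-1)
        u = np.where(
            (idx[0] < 8)[..., None],
            world @ (A_left - np.eye(3)).T,
            world @ (A_right - np.eye(3)).T,
        )
        fld = _field(u)
        t = compute_tensors(fld)
        labels = np.zeros(shape, dtype=np.uint8)
        labels[1:7, :, :] = Lobe.LUL  # interior of left block
        labels[9:15, :, :] = Lobe.RUL  # interior of right block
        summ = regional_summary(t, LobeMask(data=labels, grid=fld.grid))
        assert summ.per_region.loc["LUL", "J_median"] == pytest.approx(cf_left["J"], abs=1e-9)
        assert summ.per_region.loc["RUL", "J_median"] == pytest.approx(cf_right["J"], abs=1e-9)
        assert summ.per_region.loc["RUL", "ADI_median"] == pytest.approx(cf_right["ADI"], abs=1e-9)

    def test_empty_region_flagged(self):
        fld, _ = make_affine_displacement(AffineFieldSpec(A=np.eye(3), grid_shape=(6, 6, 6)))
        labels = np.zeros((6, 6, 6), dtype=np.uint8)
        labels[:3] = Lobe.LUL
        summ = regional_summary(compute_tensors(fld), LobeMask(data=labels, grid=fld.grid))
        assert "RUL" in summ.metadata["empty_regions"]
        assert np.isnan(summ.per_region.loc["RUL", "J_median"])


def test_folding_field_rejected():
    with pytest.raises(ValueError, match="det"):
        AffineFieldSpec(A=-np.eye(3))
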