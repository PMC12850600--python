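import numpy as np
import pytest

from pipedmri import gnl
from pipedmri import spherical as sp

from conftest import random_unit_vectors


def random_coil_model(seed, max_degree=5, eps=0.05):
    rng = np.random.default_rng(seed)
    model = gnl.CoilHarmonicModel.ideal(reference_radius_mm=200.0)
    for ax in range(3):
        for l in range(2, max_degree + 1):
            for m in range(-l, l + 1):
                model.terms[ax].append((l, m, eps * rng.normal()))
    return model


class TestExpandCoilField:
    def test_ideal_coils_give_identity(self):
        grid = gnl.VoxelGrid.centered((4, 4, 4), 50.0)
        field = gnl.expand_coil_field(gnl.CoilHarmonicModel.ideal(), grid)
        np.testing.assert_allclose(
            field.L, np.broadcast_to(np.eye(3), field.L.shape), atol=1e-13
        )

    def test_degree3_term_vanishes_at_isocenter(self):
        # single-voxel grid at the origin
        grid = gnl.VoxelGrid((1, 1, 1), np.eye(4))
        model = gnl.CoilHarmonicModel.ideal()
        model.terms[0].append((3, 1, 0.4))
        field = gnl.expand_coil_field(model, grid)
        np.testing.assert_allclose(field.L[0, 0, 0], np.eye(3), atol=1e-13)

    def test_analytic_gradient_vs_finite_differences(self):
        model = random_coil_model(seed=42)
        grid = gnl.VoxelGrid.centered((5, 5, 5), 30.0)
        field = gnl.expand_coil_field(model, grid)
        # finite-difference oracle on B_z of each coil
        h = 1e-3  # mm
        coords = grid.coords_mm()
        rref = model.reference_radius_mm
        for ax in range(3):
            def bz(pts):
                u = pts / rref
                out = np.zeros(u.shape[:-1])
                for l, m, c in model.terms[ax]:
                    out += c * gnl.solid_harmonic(l, m)(u)
                return out * rref

            for i in range(3):
                step = np.zeros(3)
                step[i] = h
                fd = (bz(coords + step) - bz(coords - step)) / (2 * h)
                rel = np.abs(field.L[..., i, ax] - fd) / max(np.abs(fd).max(), 1.0)
                assert rel.max() < 1e-4

    def test_degree0_only_model_rejected(self):
        model = gnl.CoilHarmonicModel({0: [(0, 0, 1.0)], 1: [(0, 0, 1.0)], 2: [(0, 0, 1.0)]})
        with pytest.raises(ValueError, match="degree"):
            gnl.expand_coil_field(model, gnl.VoxelGrid.centered((2, 2, 2), 10.0))


class TestEffectiveBtensor:
    def test_identity(self):
        B0 = np.array([[1.0, 0.2, 0.0], [0.2, 0.5, 0.1], [0.0, 0.1, 0.3]])
        np.testing.assert_allclose(gnl.effective_btensor(np.eye(3), B0), B0)

    def test_diagonal_algebra(self):
        L = np.diag([1.2, 1.0, 1.0])
        B0 = np.outer([1.0, 0, 0], [1.0, 0, 0])
        B = gnl.effective_btensor(L, B0)
        np.testing.assert_allclose(B, np.diag([1.44, 0.0, 0.0]), atol=1e-14)
        assert np.trace(B) == pytest.approx(1.44)

    def test_lte_rank_preserved(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            L = np.eye(3) + 0.3 * rng.normal(size=(3, 3))
            g = rng.normal(size=3)
            g /= np.linalg.norm(g)
            B = gnl.effective_btensor(L, np.outer(g, g))
            ev = np.sort(np.abs(np.linalg.eigvalsh(B)))
            assert ev[1] < 1e-12 * ev[2]

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            gnl.effective_btensor(np.eye(3), np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1.0]]))


class TestEffectiveLTE:
    def test_identity(self):
        b, g = gnl.effective_lte(np.eye(3), 1.7, [0, 1.0, 0])
        assert b == pytest.approx(1.7)
        np.testing.assert_allclose(g, [0, 1, 0])

    def test_diagonal_x(self):
        b, g = gnl.effective_lte(np.diag([1.2, 1, 1.0]), 1.0, [1.0, 0, 0])
        assert b == pytest.approx(1.44)
        np.testing.assert_allclose(g, [1, 0, 0])

    def test_diagonal_y_unchanged(self):
        b, g = gnl.effective_lte(np.diag([1.2, 1, 1.0]), 1.0, [0, 1.0, 0])
        assert b == pytest.approx(1.0)
        np.testing.assert_allclose(g, [0, 1, 0])

    def test_degenerate_direction_raises(self):
        L = np.diag([0.0, 1.0, 1.0])
        with pytest.raises(gnl.DegenerateEncodingError):
            gnl.effective_lte(L, 1.0, [1.0, 0, 0])


class TestNonlinearityDecomposition:
    def test_identity(self):
        d = gnl.nonlinearity_decomposition(np.eye(3))
        assert d.N0 == pytest.approx(1.0)
        np.testing.assert_allclose(d.N2m, 0.0, atol=1e-14)
        assert d.N2 == pytest.approx(0.0, abs=1e-14)

    def test_trace_arithmetic(self):
        d = gnl.nonlinearity_decomposition(np.diag([1.2, 1.0, 1.0]))
        assert d.N0 == pytest.approx(3.44 / 3.0)

    def test_rotation_gives_identity_N(self):
        R = sp.rotation_matrix_zyz(0.4, 1.1, -0.6)
        d = gnl.nonlinearity_decomposition(R)
        np.testing.assert_allclose(d.N, np.eye(3), atol=1e-12)
        assert d.N2 == pytest.approx(0.0, abs=1e-12)

    def test_reconstruction_exact(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            L = np.eye(3) + 0.5 * rng.normal(size=(3, 3))
            d = gnl.nonlinearity_decomposition(L)
            np.testing.assert_allclose(d.reconstruct(), d.N, atol=1e-12)

    def test_n2_zero_iff_isotropic(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            c = rng.uniform(0.5, 2.0)
            R = sp.rotation_matrix_zyz(*sp.sample_so3_uniform(1, rng)[0])
            d = gnl.nonlinearity_decomposition(np.sqrt(c) * R)
            assert d.N2 == pytest.approx(0.0, abs=1e-12)
            L = np.eye(3) + 0.3 * rng.normal(size=(3, 3))
            d = gnl.nonlinearity_decomposition(L)
            aniso = d.N - d.N0 * np.eye(3)
            if np.abs(aniso).max() > 1e-6:
                assert d.N2 > 1e-8

    def test_stf_basis_matches_spherical_module(self):
        dirs = random_unit_vectors(40, seed=9)
        M = gnl.stf_basis()
        for i, m in enumerate(range(-2, 3)):
            quad = np.einsum("ki,ij,kj->k", dirs, M[i], dirs)
            np.testing.assert_allclose(quad, sp.sh_real(2, m, dirs), atol=1e-12)


class TestDirectionalStats:
    def test_identity(self):
        d = gnl.nonlinearity_decomposition(np.eye(3))
        assert gnl.directional_stats(d) == (1.0, 0.0)

    def test_frozen_diag_example(self):
        # N = diag(1.44, 1, 1): mean 1.146667, variance 4/45 * 0.44^2
        d = gnl.nonlinearity_decomposition(np.diag([1.2, 1.0, 1.0]))
        mean, std = gnl.directional_stats(d)
        assert mean == pytest.approx(1.1466666667)
        assert std**2 == pytest.approx(0.0172088889, rel=1e-8)
        assert std == pytest.approx(0.131182, rel=1e-4)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(10)
        v = random_unit_vectors(400_000, seed=11)
        for _ in range(5):
            L = np.eye(3) + 0.4 * rng.normal(size=(3, 3))
            d = gnl.nonlinearity_decomposition(L)
            mean, std = gnl.directional_stats(d)
            Ng = np.einsum("ki,ij,kj->k", v, d.N, v)
            n = v.shape[0]
            se_mean = Ng.std() / np.sqrt(n)
            assert abs(mean - Ng.mean()) < 3 * se_mean
            se_std = Ng.std() / np.sqrt(2.0 * n)
            assert abs(std - Ng.std()) < 3 * max(se_std, 1e-12)


class TestDeformProtocol:
    def make_protocol(self):
        g = np.vstack([np.eye(3), -np.eye(3)])
        return gnl.NominalProtocol(np.ones(6), g)

    def test_identity_field_passthrough(self):
        grid = gnl.VoxelGrid.centered((3, 3, 3), 20.0)
        field = gnl.GradientCoilTensorField.identity(grid)
        nominal = self.make_protocol()
        vp = gnl.deform_protocol(field, nominal)
        np.testing.assert_allclose(vp.b, np.broadcast_to(nominal.b, vp.b.shape), atol=1e-14)
        np.testing.assert_allclose(vp.g, np.broadcast_to(nominal.g, vp.g.shape), atol=1e-14)

    def test_single_voxel_diag(self):
        grid = gnl.VoxelGrid((1, 1, 1), np.eye(4))
        field = gnl.GradientCoilTensorField(grid, np.diag([1.2, 1.0, 1.0])[None, None, None])
        vp = gnl.deform_protocol(field, self.make_protocol())
        np.testing.assert_allclose(
            np.sort(vp.b[0, 0, 0]), [1, 1, 1, 1, 1.44, 1.44], atol=1e-12
        )

    def test_b_ratio_matches_decomposition(self):
        rng = np.random.default_rng(12)
        L = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
        grid = gnl.VoxelGrid((1, 1, 1), np.eye(4))
        field = gnl.GradientCoilTensorField(grid, L[None, None, None])
        g0 = random_unit_vectors(10, seed=13)
        nominal = gnl.NominalProtocol(np.full(10, 2.0), g0)
        vp = gnl.deform_protocol(field, nominal)
        d = gnl.nonlinearity_decomposition(L)
        for k in range(10):
            want = d.N0 + sum(
                d.N2m[i] * sp.sh_real(2, m, g0[k]) for i, m in enumerate(range(-2, 3))
            )
            assert vp.b[0, 0, 0, k] / 2.0 == pytest.approx(want, rel=1e-10)

    def test_b0_volumes_pass_through(self):
        grid = gnl.VoxelGrid((1, 1, 1), np.eye(4))
        field = gnl.GradientCoilTensorField(grid, np.diag([2.0, 1.0, 1.0])[None, None, None])
        nominal = gnl.NominalProtocol(np.array([0.0, 1.0]), np.array([[0, 0, 1.0], [1.0, 0, 0]]))
        vp = gnl.deform_protocol(field, nominal)
        assert vp.b[0, 0, 0, 0] == 0.0
        np.testing.assert_allclose(vp.g[0, 0, 0, 0], gnl.B0_DIRECTION)

    def test_empty_protocol_rejected(self):
        grid = gnl.VoxelGrid((1, 1, 1), np.eye(4))
        field = gnl.GradientCoilTensorField.identity(grid)
        with pytest.raises(ValueError):
            gnl.deform_protocol(field, gnl.NominalProtocol(np.zeros(0), np.zeros((0, 3))))


class TestMotionAdjustedBtensor:
    def make_field(self):
        grid = gnl.VoxelGrid.centered((9, 9, 9), 10.0)
        model = gnl.CoilHarmonicModel.ideal(reference_radius_mm=60.0)
        model.terms[0].append((3, 2, 0.3))
        model.terms[2].append((3, -1, 0.2))
        return gnl.expand_coil_field(model, grid)

    def test_no_motion_reduces_to_effective_btensor(self):
        field = self.make_field()
        B0 = 2.0 * np.outer([0, 0, 1.0], [0, 0, 1.0])
        r = np.array([12.0, -8.0, 4.0])
        got = gnl.motion_adjusted_btensor(field, B0, np.eye(3), np.zeros(3), r)
        L = field.sample_mm(r)
        np.testing.assert_allclose(got, gnl.effective_btensor(L, B0), atol=1e-12)

    def test_identity_field_rotates_b0(self):
        grid = gnl.VoxelGrid.centered((5, 5, 5), 10.0)
        field = gnl.GradientCoilTensorField.identity(grid)
        R = sp.rotation_matrix_zyz(0.3, 0.8, -0.2)
        B0 = np.outer([1.0, 0, 0], [1.0, 0, 0])
        got = gnl.motion_adjusted_btensor(field, B0, R, np.array([1.0, 2.0, -1.0]), np.zeros(3))
        np.testing.assert_allclose(got, R @ B0 @ R.T, atol=1e-12)

    def test_translation_to_isocenter_oracle(self):
        field = self.make_field()
        R = sp.rotation_matrix_zyz(0.5, 0.4, 0.1)
        t = np.array([3.0, -2.0, 1.0])
        r = t.copy()  # r0 = R^-1 (r - t) = 0, where L = I
        B0 = np.outer([0, 1.0, 0], [0, 1.0, 0])
        got = gnl.motion_adjusted_btensor(field, B0, R, t, r)
        np.testing.assert_allclose(got, R @ B0 @ R.T, atol=1e-10)

    def test_out_of_grid_clamps_with_warning(self):
        field = self.make_field()
        B0 = np.outer([1.0, 0, 0], [1.0, 0, 0])
        with pytest.warns(UserWarning, match="clamping"):
            gnl.motion_adjusted_btensor(field, B0, np.eye(3), np.zeros(3), np.array([500.0, 0, 0]))
        with pytest.raises(ValueError, match="outside"):
            gnl.motion_adjusted_btensor(
                field, B0, np.eye(3), np.zeros(3), np.array([500.0, 0, 0]), strict=True
            )

    def test_improper_rotation_rejected(self):
        field = self.make_field()
        with pytest.raises(ValueError, match="rotation"):
            gnl.motion_adjusted_btensor(
                field, np.eye(3), np.diag([1.0, 1.0, -1.0]), np.zeros(3), np.zeros(3)
            )


class TestProtocolValidation:
    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            gnl.NominalProtocol(np.array([-1.0]), np.array([[0, 0, 1.0]]))

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            gnl.NominalProtocol(np.array([1.0]), np.array([[0, 0, 2.0]]))

    def test_mean_over_directions_is_n0_random(self):
        rng = np.random.default_rng(20)
        v = random_unit_vectors(200_000, seed=21)
        L = np.eye(3) + 0.6 * rng.normal(size=(3, 3))
        d = gnl.nonlinearity_decomposition(L)
        Ng = np.einsum("ki,ij,kj->k", v, d.N, v)
        assert abs(Ng.mean() - d.N0) < 3 * Ng.std() / np.sqrt(v.shape[0])


# ---------------------------------------------------------------------------
# property tests

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


l_matrices = arrays(
    np.float64, (3, 3), elements=st.floats(-0.5, 0.5, allow_nan=False)
).map(lambda a: np.eye(3) + a)


@settings(max_examples=50, deadline=None)
@given(l_matrices)
def test_decomposition_reconstruction_property(L):
    d = gnl.nonlinearity_decomposition(L)
    np.testing.assert_allclose(d.reconstruct(), d.N, atol=1e-12)
    assert d.N2 >= 0
    assert d.N0 == pytest.approx(np.trace(d.N) / 3.0)


@settings(max_examples=30, deadline=None)
@given(l_matrices, st.integers(0, 10_000))
def test_lte_b_value_matches_quadratic_form(L, dir_seed):
    g0 = np.random.default_rng(dir_seed).normal(size=3)
    if np.linalg.norm(g0) < 1e-6 or np.linalg.norm(L @ (g0 / np.linalg.norm(g0))) < 1e-6:
        return
    g0 /= np.linalg.norm(g0)
    b, g = gnl.effective_lte(L, 1.0, g0)
    assert b == pytest.approx(g0 @ (L.T @ L) @ g0, abs=1e-12)
    assert np.linalg.norm(g) == pytest.approx(1.0)
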