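import numpy as np
import pytest

from pipedmri import estimation as est
from pipedmri import factorization as fz
from pipedmri import gnl
from pipedmri import kernel as kn
from pipedmri import phantom as ph
from pipedmri import spherical as sp
from pipedmri import training as tr

from conftest import random_unit_vectors


def forward_gamma(basis, xi, fodf_values):
    """Oracle: gamma_nlm = s_n v_n(xi) p_lm in design-matrix column order."""
    v = fz.project_v(basis, xi)
    out = []
    for l in basis.ells:
        i0 = sp.sh_index(l, -l)
        for n in range(basis.n_components(l)):
            for m in range(-l, l + 1):
                out.append(basis.s[l][n] * v[l][n] * fodf_values[i0 + m + l])
    return np.array(out)


@pytest.fixture(scope="module")
def voxel(basis, ref_protocol):
    xi = kn.SMKernelParams(0.55, 2.2, 1.8, 0.7, 0.12)
    arr, _ = tr.sample_fodf_batch(1, 42, lmax=2)
    fodf = sp.SHCoefficients(2, arr[0])
    S = kn.convolve_signal(xi, fodf, ref_protocol.b, ref_protocol.g)
    return xi, fodf, S


class TestDesignMatrix:
    def test_l0_columns_equal_interp_u(self, basis, ref_protocol):
        dm = est.design_matrix(basis, ref_protocol.b, ref_protocol.g)
        U = fz.interp_u(basis, 0, ref_protocol.b)
        for n in range(basis.n_components(0)):
            col = dm.alpha[:, dm.columns.index((n, 0, 0))]
            np.testing.assert_allclose(col, U[:, n], atol=1e-14)

    def test_entries_match_independent_recomputation(self, basis, ref_protocol):
        dm = est.design_matrix(basis, ref_protocol.b, ref_protocol.g)
        dw = ref_protocol.b > 0
        for c, (n, l, m) in enumerate(dm.columns):
            want = fz.interp_u(basis, l, ref_protocol.b, n=n) * sp.sh_real(
                l, m, ref_protocol.g
            )
            if l > 0:
                want = np.where(dw, want, 0.0)
            np.testing.assert_allclose(dm.alpha[:, c], want, atol=1e-14)

    def test_column_count(self, basis, ref_protocol):
        dm = est.design_matrix(basis, ref_protocol.b, ref_protocol.g)
        assert dm.alpha.shape[1] == basis.n_columns
        assert basis.n_columns == 4 * 1 + 3 * 5

    def test_b0_only_protocol_flags_l2_deficient(self, basis):
        b = np.zeros(10)
        g = np.tile([0, 0, 1.0], (10, 1))
        dm = est.design_matrix(basis, b, g)
        assert any(l == 2 for l, n in dm.deficient_blocks)
        with pytest.raises(est.ConditioningError):
            est.fit_gamma(dm, np.ones(10))


class TestFitGamma:
    def test_noiseless_recovers_forward_gamma(self, basis, ref_protocol, voxel):
        xi, fodf, S = voxel
        dm = est.design_matrix(basis, ref_protocol.b, ref_protocol.g)
        gam = est.fit_gamma(dm, S)
        want = forward_gamma(basis, xi, fodf.values)
        # limited by SVD truncation of the kernel (documented tolerance)
        assert np.abs(gam - want).max() / np.abs(want).max() < 1e-3

    def test_linearity(self, basis, ref_protocol, voxel):
        _, _, S = voxel
        dm = est.design_matrix(basis, ref_protocol.b, ref_protocol.g)
        np.testing.assert_allclose(
            est.fit_gamma(dm, 3.7 * S), 3.7 * est.fit_gamma(dm, S), atol=1e-12
        )

    def test_cross_protocol_consistency(self, basis, voxel):
        # identical tissue under different deformed protocols -> same gamma
        xi, fodf, _ = voxel
        nominal = ph.make_shelled_protocol(n_b0=5, seed=1)
        rng = np.random.default_rng(0)
        gams = []
        for trial in range(3):
            L = np.eye(3) + 0.05 * rng.normal(size=(3, 3))
            b, g = gnl.effective_lte(L, nominal.b, nominal.g)
            b = np.where(nominal.b > 0, b, 0.0)
            S = kn.convolve_signal(xi, fodf, b, g)
            dm = est.design_matrix(basis, b, g)
            gams.append(est.fit_gamma(dm, S))
        gams = np.array(gams)
        spread = np.abs(gams.max(0) - gams.min(0)).max() / np.abs(gams).max()
        assert spread < 1e-2

    def test_non_finite_signal_rejected(self, basis, ref_protocol):
        dm = est.design_matrix(basis, ref_protocol.b, ref_protocol.g)
        S = np.ones(len(ref_protocol))
        S[3] = np.nan
        with pytest.raises(ValueError):
            est.fit_gamma(dm, S)

    def test_gaussian_noise_covariance(self, basis, ref_protocol, voxel):
        # cov(gamma) = sigma^2 pinv pinv^T, MC with 1e4 replicates
        _, _, S = voxel
        dm = est.design_matrix(basis, ref_protocol.b, ref_protocol.g)
        sigma = 1.0 / 50.0
        rng = np.random.default_rng(77)
        eps = rng.normal(scale=sigma, size=(10_000, S.size))
        gam = (S + eps) @ dm.pinv.T
        want = sigma**2 * np.diag(dm.pinv @ dm.pinv.T)
        got = gam.var(axis=0)
        assert np.abs(got / want - 1.0).max() < 0.10


class TestFitVolume:
    def test_identity_field_shares_one_pinv(self, basis, ref_protocol):
        grid = gnl.VoxelGrid.centered((3, 3, 2), 20.0)
        field = gnl.GradientCoilTensorField.identity(grid)
        protocols = gnl.deform_protocol(field, ref_protocol)
        xi = kn.SMKernelParams(0.5, 2.0, 1.6, 0.6, 0.1)
        fodf = sp.SHCoefficients(2)
        fodf[0, 0] = 1.0
        S = kn.convolve_signal(xi, fodf, ref_protocol.b, ref_protocol.g)
        data = np.broadcast_to(S, (*grid.shape, S.size)).copy()
        gf = est.fit_volume(basis, data, protocols)
        assert gf.qc["n_unique_protocols"] == 1
        dm = est.design_matrix(basis, ref_protocol.b, ref_protocol.g)
        single = est.fit_gamma(dm, S)
        np.testing.assert_allclose(
            gf.gamma, np.broadcast_to(single, gf.gamma.shape), atol=1e-12
        )

    def test_all_zero_voxel_masked(self, basis, ref_protocol):
        grid = gnl.VoxelGrid.centered((2, 1, 1), 20.0)
        field = gnl.GradientCoilTensorField.identity(grid)
        protocols = gnl.deform_protocol(field, ref_protocol)
        data = np.ones((2, 1, 1, len(ref_protocol)))
        data[1] = 0.0
        gf = est.fit_volume(basis, data, protocols)
        assert gf.mask[0, 0, 0]
        assert not gf.mask[1, 0, 0]
        assert gf.qc["errors"]


class TestGammaInvariants:
    def test_noiseless_forward_oracle(self, basis):
        xi = kn.SMKernelParams(0.6, 2.4, 1.9, 0.8, 0.05)
        arr, _ = tr.sample_fodf_batch(1, 5, lmax=2)
        gam = forward_gamma(basis, xi, arr[0])
        ells = basis.ells
        npl = {l: basis.n_components(l) for l in ells}
        inv = est.gamma_invariants(gam, ells, npl)
        v = fz.project_v(basis, xi)
        i0 = sp.sh_index(2, -2)
        p2 = np.sqrt(np.sum(arr[0][i0 : i0 + 5] ** 2) / 5.0)
        want = []
        for l in ells:
            pl = 1.0 if l == 0 else p2
            sv1 = basis.s[l][0] * v[l][0]
            want.append(abs(sv1) * pl)
            for n in range(1, npl[l]):
                want.append(abs(sv1) * pl * (basis.s[l][n] * v[l][n]) / sv1)
        np.testing.assert_allclose(inv, want, atol=1e-6)

    def test_isotropic_fodf_missing_l2(self, basis):
        xi = kn.SMKernelParams(0.5, 2.0, 1.5, 0.5, 0.1)
        p = np.zeros(sp.n_coeffs(2))
        p[0] = 1.0
        gam = forward_gamma(basis, xi, p)
        ells = basis.ells
        npl = {l: basis.n_components(l) for l in ells}
        inv = est.gamma_invariants(gam, ells, npl)
        assert np.all(np.isfinite(inv[:4]))
        assert np.all(np.isnan(inv[4:]))

    def test_rotation_invariance(self, basis):
        xi = kn.SMKernelParams(0.5, 2.0, 1.5, 0.5, 0.1)
        arr, _ = tr.sample_fodf_batch(1, 6, lmax=2)
        fodf = sp.SHCoefficients(2, arr[0])
        rot = sp.wigner_rotate(fodf, (0.3, 1.0, -0.7))
        ells = basis.ells
        npl = {l: basis.n_components(l) for l in ells}
        a = est.gamma_invariants(forward_gamma(basis, xi, fodf.values), ells, npl)
        b = est.gamma_invariants(forward_gamma(basis, xi, rot.values), ells, npl)
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestResampleSignal:
    def test_round_trip_at_acquired_protocol(self, basis, ref_protocol, voxel):
        xi, fodf, S = voxel
        dm = est.design_matrix(basis, ref_protocol.b, ref_protocol.g)
        gam = est.fit_gamma(dm, S)
        recon = dm.alpha @ gam
        assert np.abs(recon - S).max() < 2e-3  # truncation tolerance

    def test_s0_at_b0_is_one(self, basis, ref_protocol, voxel):
        _, _, S = voxel
        dm = est.design_matrix(basis, ref_protocol.b, ref_protocol.g)
        gam = est.fit_gamma(dm, S)
        ells = basis.ells
        npl = {l: basis.n_components(l) for l in ells}
        dirs = ph.uniform_directions(32, seed=4)
        _, sl = est.resample_signal(gam, ells, npl, basis, [0.0], dirs)
        assert sl[0, 0] == pytest.approx(1.0, abs=2e-3)

    def test_isotropic_voxel_zero_s2(self, basis, ref_protocol):
        xi = kn.SMKernelParams(0.0, 2.0, 1.5, 1.5, 0.3)
        fodf = sp.SHCoefficients(2)
        fodf[0, 0] = 1.0
        S = kn.convolve_signal(xi, fodf, ref_protocol.b, ref_protocol.g)
        dm = est.design_matrix(basis, ref_protocol.b, ref_protocol.g)
        gam = est.fit_gamma(dm, S)
        dirs = ph.uniform_directions(32, seed=4)
        _, sl = est.resample_signal(
            gam,
            basis.ells,
            {l: basis.n_components(l) for l in basis.ells},
            basis,
            [1.0, 2.0, 4.0],
            dirs,
        )
        assert np.abs(sl[:, 1]).max() < 2e-3

    def test_shelled_equivalence_with_per_shell_sh_fit(self, basis, ref_protocol):
        # signals synthesized from the factorized model itself: the
        # conventional per-shell SH fit and the gamma-derived invariants
        # must agree to numerical precision
        rng = np.random.default_rng(9)
        gam = rng.normal(size=basis.n_columns)
        ells = basis.ells
        npl = {l: basis.n_components(l) for l in ells}
        dm = est.design_matrix(basis, ref_protocol.b, ref_protocol.g)
        S = dm.alpha @ gam
        for shell_b in (1.0, 2.0, 8.0):
            sel = np.isclose(ref_protocol.b, shell_b)
            g = ref_protocol.g[sel]
            Y = sp.sh_real_block(2, g)
            coef, *_ = np.linalg.lstsq(Y, S[sel], rcond=None)
            fit_inv = [
                np.sqrt(np.sum(coef[sp.sh_index(l, -l) : sp.sh_index(l, l) + 1] ** 2) / (2 * l + 1))
                for l in ells
            ]
            _, sl = est.resample_signal(gam, ells, npl, basis, [shell_b], g)
            np.testing.assert_allclose(sl[0], fit_inv, atol=1e-6)


class TestEndToEndIdentifiability:
    def test_hundred_random_voxels(self, basis, ref_protocol):
        xi_tab = tr.sample_kernel_priors(100, 31)
        arr, _ = tr.sample_fodf_batch(100, 32, lmax=2)
        b = np.tile(ref_protocol.b, (100, 1))
        g = np.tile(ref_protocol.g, (100, 1, 1))
        S = ph.simulate_signals(xi_tab, arr, b, g, 2)
        dm = est.design_matrix(basis, ref_protocol.b, ref_protocol.g)
        gam = S @ dm.pinv.T
        for i in range(100):
            want = forward_gamma(basis, kn.SMKernelParams.from_array(xi_tab[i]), arr[i])
            # combined truncation + interpolation tolerance over the prior box
            assert np.abs(gam[i] - want).max() / np.abs(want).max() < 2e-2
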