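import itertools

import numpy as np
import pytest

from gmrid import (
    DiffusionParams,
    NoiseModel,
    SpectralProjection,
    apply_global_filter,
    denoise,
    estimate_mse_proxy,
    generate_phantom,
    add_gaussian_noise,
    project,
    psnr,
    select_diffusion,
)
from gmrid.nystrom_filter import FilterSpectrum, dense_filter_spectrum
from gmrid.patch_kernel import KernelSpec


def random_spectrum(rng, n=30, m=8):
    """Orthonormal random spectrum with eigenvalues in (0, 1], leading 1."""
    Q, _ = np.linalg.qr(rng.normal(size=(n, m)))
    vals = np.sort(rng.uniform(0.01, 1.0, size=m))[::-1]
    vals[0] = 1.0
    return FilterSpectrum(eigvecs=Q, eigvals=vals, sample_order=np.arange(n))


class TestProject:
    def test_eigenvector_projects_to_unit_coeff(self, rng):
        sp = random_spectrum(rng)
        proj = project(sp, sp.eigvecs[:, 0])
        expect = np.zeros(sp.m)
        expect[0] = 1.0
        np.testing.assert_allclose(proj.coeffs, expect, atol=1e-10)

    def test_zero_input(self, rng):
        sp = random_spectrum(rng)
        proj = project(sp, np.zeros(sp.n))
        assert np.all(proj.coeffs == 0) and np.all(proj.shrunk_b2 == 0)

    def test_no_shrinkage_at_zero_sigma(self, rng):
        sp = random_spectrum(rng)
        y = rng.normal(size=sp.n)
        proj = project(sp, y, sigma=0.0)
        np.testing.assert_array_equal(proj.shrunk_b2, proj.coeffs**2)

    def test_shrinkage_subtracts_noise_floor(self, rng):
        sp = random_spectrum(rng)
        y = rng.normal(size=sp.n)
        proj = project(sp, y, sigma=0.5)
        np.testing.assert_allclose(
            proj.shrunk_b2, np.maximum(proj.coeffs**2 - 0.25, 0.0), atol=1e-14
        )

    def test_dimension_mismatch(self, rng):
        sp = random_spectrum(rng)
        with pytest.raises(ValueError):
            project(sp, np.zeros(sp.n + 1))


class TestMseProxy:
    def test_hand_computed_values(self):
        # lam=1, b2=4, sigma2=1, k=1, m=1: (1-2)*4 + 1 = -3
        proj = SpectralProjection(coeffs=np.array([2.0]), shrunk_b2=np.array([4.0]))
        val = estimate_mse_proxy(np.array([1.0]), proj, 1.0, DiffusionParams(k=1, m=1))
        assert val == pytest.approx(-3.0)
        # lam=0.5, b2=1, sigma=0, k=2: 0.5^4 - 2*0.5^2 = -0.4375
        proj = SpectralProjection(coeffs=np.array([1.0]), shrunk_b2=np.array([1.0]))
        val = estimate_mse_proxy(np.array([0.5]), proj, 0.0, DiffusionParams(k=2, m=1))
        assert val == pytest.approx(-0.4375)

    def test_nonincreasing_in_m_at_zero_sigma(self, rng):
        for _ in range(10):
            m = 12
            lam = np.sort(rng.uniform(0.01, 1.0, size=m))[::-1]
            b2 = rng.uniform(0, 4, size=m)
            proj = SpectralProjection(coeffs=np.sqrt(b2), shrunk_b2=b2)
            vals = [
                estimate_mse_proxy(lam, proj, 0.0, DiffusionParams(k=1.5, m=mm))
                for mm in range(1, m + 1)
            ]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_negative_sigma_rejected(self):
        proj = SpectralProjection(coeffs=np.array([1.0]), shrunk_b2=np.array([1.0]))
        with pytest.raises(ValueError):
            estimate_mse_proxy(np.array([1.0]), proj, -1.0, DiffusionParams(k=1, m=1))


def brute_force_argmin(lam, b2, sigma, k_grid, m_grid):
    best = None
    for k, m in itertools.product(k_grid, m_grid):
        lk = lam[:m] ** k
        val = np.sum((lk**2 - 2 * lk) * b2[:m] + sigma**2 * lk**2)
        if best is None or val < best[0] - 0:
            if best is None or val < best[0]:
                best = (val, k, m)
    return best[1], best[2]


class TestSelectDiffusion:
    def test_matches_bruteforce_on_random_instances(self, rng):
        k_grid = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        for _ in range(30):
            m_max = 10
            lam = np.sort(rng.uniform(0.0, 1.0, size=m_max))[::-1]
            lam[0] = 1.0
            b2 = rng.uniform(0, 2, size=m_max)
            sigma = rng.uniform(0, 1)
            proj = SpectralProjection(coeffs=np.sqrt(b2), shrunk_b2=b2)
            m_grid = np.arange(1, m_max + 1)
            got = select_diffusion(lam, proj, sigma, k_grid, m_grid)
            bk, bm = brute_force_argmin(lam, b2, sigma, k_grid, m_grid)
            lk = lam[:got.m] ** got.k
            got_val = np.sum((lk**2 - 2 * lk) * b2[:got.m] + sigma**2 * lk**2)
            lk = lam[:bm] ** bk
            best_val = np.sum((lk**2 - 2 * lk) * b2[:bm] + sigma**2 * lk**2)
            assert got_val == pytest.approx(best_val, abs=1e-12)

    def test_zero_sigma_selects_min_k_max_m(self, rng):
        lam = np.sort(rng.uniform(0.1, 1.0, size=6))[::-1]
        b2 = rng.uniform(0.1, 2.0, size=6)
        proj = SpectralProjection(coeffs=np.sqrt(b2), shrunk_b2=b2)
        params = select_diffusion(lam, proj, 0.0, np.array([0.5, 1, 2]), np.arange(1, 7))
        assert params.k == 0.5 and params.m == 6

    def test_pure_noise_mode_prefers_stronger_diffusion(self):
        # single mode lam=0.5 carrying no signal: sigma^2 lam^{2k} decreasing in k
        proj = SpectralProjection(coeffs=np.array([0.0]), shrunk_b2=np.array([0.0]))
        params = select_diffusion(np.array([0.5]), proj, 1.0, np.array([1.0, 2.0]), np.array([1]))
        assert params.k == 2.0

    def test_empty_grid_rejected(self, rng):
        proj = SpectralProjection(coeffs=np.array([1.0]), shrunk_b2=np.array([1.0]))
        with pytest.raises(ValueError):
            select_diffusion(np.array([1.0]), proj, 0.0, np.array([]), np.array([1]))


class TestApplyGlobalFilter:
    def test_identity_when_unit_eigenvalues_full_rank(self, rng):
        n = 20
        Q, _ = np.linalg.qr(rng.normal(size=(n, n)))
        sp = FilterSpectrum(eigvecs=Q, eigvals=np.ones(n), sample_order=np.arange(n))
        y = rng.normal(size=n)
        out = apply_global_filter(sp, y, DiffusionParams(k=3, m=n))
        np.testing.assert_allclose(out, y, atol=1e-10)

    def test_matches_dense_matrix_power(self, random_volume):
        # n <= 200, full spectrum: V E^k V^T y == W^k y by repeated multiply
        vol = random_volume(shape=(5, 5, 5), seed=2)
        spectrum, _ = dense_filter_spectrum(vol, KernelSpec(bandwidth_h=0.3), tol=1e-10)
        W = (spectrum.eigvecs * spectrum.eigvals) @ spectrum.eigvecs.T
        y = np.random.default_rng(0).normal(size=vol.n)
        for k in (1, 3):
            expect = y.copy()
            for _ in range(k):
                expect = W @ expect
            got = apply_global_filter(spectrum, y, DiffusionParams(k=k, m=vol.n))
            np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_large_k_collapses_to_leading_mode(self, random_volume):
        vol = random_volume(shape=(4, 4, 4), seed=5)
        spectrum, _ = dense_filter_spectrum(vol, KernelSpec(bandwidth_h=0.3), tol=1e-12)
        y = np.random.default_rng(1).normal(size=vol.n)
        got = apply_global_filter(spectrum, y, DiffusionParams(k=400, m=vol.n))
        v1 = spectrum.eigvecs[:, 0]
        np.testing.assert_allclose(got, v1 * (v1 @ y), atol=1e-5)

    def test_linearity(self, rng):
        sp = random_spectrum(rng, n=25, m=6)
        y1, y2 = rng.normal(size=25), rng.normal(size=25)
        p = DiffusionParams(k=2.5, m=6)
        lhs = apply_global_filter(sp, 2.0 * y1 - 3.0 * y2, p)
        rhs = 2.0 * apply_global_filter(sp, y1, p) - 3.0 * apply_global_filter(sp, y2, p)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_sample_order_respected(self, rng):
        # a spectrum stored in permuted (sample-first) row order must act
        # identically to the same spectrum stored in voxel order
        sp = random_spectrum(rng, n=12, m=4)
        y = rng.normal(size=12)
        perm = rng.permutation(12)
        sp_perm = FilterSpectrum(
            eigvecs=sp.eigvecs[perm], eigvals=sp.eigvals, sample_order=perm
        )
        p = DiffusionParams(k=1.0, m=4)
        np.testing.assert_allclose(
            apply_global_filter(sp, y, p), apply_global_filter(sp_perm, y, p), atol=1e-12
        )


class TestDenoisePipeline:
    def test_near_zero_noise_returns_input(self):
        # full sampling + full rank: selection reaches the identity
        ph = generate_phantom((8, 8, 8), seed=0)
        nm = NoiseModel("gaussian", 1e-6)
        res = denoise(ph.truth, nm, rate=1.0, rank=512, seed=0)
        assert np.max(np.abs(res.volume.data - ph.truth.data)) <= 1e-3

    def test_variance_reduction_on_constant_plus_noise(self):
        import gmrid

        reduced = 0
        for seed in range(5):
            base = gmrid.Volume(np.full((10, 10, 10), 0.5))
            noisy = add_gaussian_noise(base, 10.0, seed=seed)
            # absolute sigma 0.05 maps to ~0.125 on the rescaled range
            span = noisy.data.max() - noisy.data.min()
            nm = NoiseModel("gaussian", 0.05 / span)
            res = denoise(noisy, nm, rank=30, rate=0.05, seed=seed)
            if res.volume.data.var() < noisy.data.var():
                reduced += 1
        assert reduced >= 4

    def test_psnr_improves_on_noisy_phantom(self):
        ph = generate_phantom((16, 16, 16), seed=0)
        noisy = add_gaussian_noise(ph.truth, 10.0, seed=1)
        res = denoise(noisy, NoiseModel("gaussian", 0.1), rank=60, rate=0.03, seed=0)
        assert psnr(ph.truth, res.volume) > psnr(ph.truth, noisy)

    def test_seed_determinism_bitwise(self):
        ph = generate_phantom((10, 10, 10), seed=2)
        noisy = add_gaussian_noise(ph.truth, 10.0, seed=3)
        nm = NoiseModel("gaussian", 0.1)
        a = denoise(noisy, nm, rank=40, rate=0.05, seed=9)
        b = denoise(noisy, nm, rank=40, rate=0.05, seed=9)
        assert np.array_equal(a.volume.data, b.volume.data)
        assert (a.k_hat, a.m_hat) == (b.k_hat, b.m_hat)

    def test_rate_below_rank_clamps_with_warning(self, caplog):
        ph = generate_phantom((8, 8, 8), seed=1)
        noisy = add_gaussian_noise(ph.truth, 5.0, seed=0)
        with caplog.at_level("WARNING", logger="gmrid"):
            res = denoise(noisy, NoiseModel("gaussian", 0.05), rank=30, rate=0.001, seed=0)
        assert res.diagnostics["landmarks"] == 30
        assert any("clamping" in r.message for r in caplog.records)

    def test_invalid_inputs(self):
        ph = generate_phantom((8, 8, 8), seed=0)
        with pytest.raises(ValueError):
            NoiseModel("gaussian", 0.0)
        with pytest.raises(ValueError):
            denoise(ph.truth, NoiseModel("gaussian", 0.1), rate=1.5)
        with pytest.raises(ValueError):
            denoise(ph.truth, NoiseModel("gaussian", 0.1), scheme="sobol")
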