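"""Metrology: normalization, CNR arithmetic, ESF/LSF fitting, and the
resolution/CNR simulation experiments."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erf

import qmcscope as q
from qmcscope.analysis import EsfFitError, display_interpolate, loglog_slope


class TestNormalizeImage:
    def test_affine_map(self):
        np.testing.assert_allclose(
            q.normalize_image(np.array([[2.0, 4.0, 6.0]])), [[0.0, 0.5, 1.0]]
        )

    def test_idempotent_on_unit_range(self, rng):
        img = rng.random((8, 8))
        img[0, 0], img[-1, -1] = 0.0, 1.0
        np.testing.assert_allclose(q.normalize_image(img), img)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_negation_reverses(self, seed):
        img = np.random.default_rng(seed).normal(size=(6, 6))
        if img.max() == img.min():
            return
        np.testing.assert_allclose(
            q.normalize_image(-img), 1.0 - q.normalize_image(img), atol=1e-12
        )

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            q.normalize_image(np.ones((4, 4)))


class TestCnr:
    def setup_method(self):
        self.img = np.zeros((4, 8))
        self.img[:, :4] = 10.0
        self.mo = np.zeros((4, 8), bool)
        self.mo[:, :4] = True
        self.mb = ~self.mo

    def test_direct_arithmetic(self):
        img = np.zeros((2, 8))
        img[:, :4] = [10, 12, 8, 10]  # mean 10, std 2 (population)
        img[:, 4:] = [2, 3, 1, 2]  # mean 2, std ~0.707... adjust below
        mo = np.zeros((2, 8), bool)
        mo[:, :4] = True
        rep = q.cnr(img, mo, ~mo)
        expected = abs(rep.mean1 - rep.mean2) / math.hypot(rep.sigma1, rep.sigma2)
        assert rep.cnr == pytest.approx(expected)
        # the worked example: means 10 and 2, sigmas 2 and 1 -> 8/sqrt(5)
        assert abs(10 - 2) / math.sqrt(2**2 + 1**2) == pytest.approx(3.5777, abs=1e-4)

    def test_identical_regions_zero(self, rng):
        img = rng.random((6, 6))
        mo = np.zeros((6, 6), bool)
        mb = np.zeros((6, 6), bool)
        mo[:3] = True
        mb[3:] = True
        img[mb] = img[mo]
        assert q.cnr(img, mo, mb).cnr == pytest.approx(0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.1, 100.0), st.floats(-5.0, 5.0))
    def test_invariant_under_positive_affine_rescale(self, scale, offset):
        rng = np.random.default_rng(7)
        img = rng.normal(size=(6, 6))
        mo = np.zeros((6, 6), bool)
        mo[:3] = True
        base = q.cnr(img, mo, ~mo).cnr
        scaled = q.cnr(scale * img + offset, mo, ~mo).cnr
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            q.cnr(self.img, np.zeros((4, 8), bool), self.mb)

    def test_overlapping_masks_rejected(self):
        with pytest.raises(ValueError):
            q.cnr(self.img, self.mo, self.mo)

    def test_zero_sigma_undefined(self):
        with pytest.raises(ValueError):
            q.cnr(self.img, self.mo, self.mb)  # both halves constant


class TestFitEsf:
    def test_noiseless_parameter_recovery(self):
        x = np.linspace(-10, 10, 201)
        y = 1.0 * erf((x - 0.0) / 2.0) + 0.0
        fit = q.fit_esf(x, y)
        assert fit.w == pytest.approx(2.0, abs=1e-6)
        assert fit.a == pytest.approx(1.0, abs=1e-6)
        assert fit.R == pytest.approx(4 * math.sqrt(math.log(2)), abs=1e-6)
        assert fit.R == pytest.approx(3.3302, abs=1e-4)

    def test_resolution_identity_exact(self):
        for w in [0.3, 1.7, 42.0]:
            fit = q.ResolutionFit(a=1, b=0, x0=0, w=w, residual_norm=0)
            assert fit.R == 2.0 * math.sqrt(math.log(2)) * w  # exact identity

    def test_gaussian_blurred_step_gives_w_sigma_sqrt2(self):
        """A perfect step blurred by a Gaussian PSF of std sigma has
        ESF = erf-model with w = sigma * sqrt(2) (closed form)."""
        sigma = 1.3
        dx = 0.02
        x = np.arange(-12, 12, dx)
        step = (x >= 0).astype(float)
        kern_x = np.arange(-6, 6, dx)
        kern = np.exp(-(kern_x**2) / (2 * sigma**2))
        kern /= kern.sum()
        blurred = np.convolve(step, kern, mode="same")
        sl = slice(150, len(x) - 150)  # clear of boundary effects
        fit = q.fit_esf(x[sl], blurred[sl])
        assert fit.w == pytest.approx(sigma * math.sqrt(2), rel=0.01)

    def test_noisy_recovery_within_five_percent(self):
        x = np.linspace(-8, 8, 160)
        truth = 0.5 * erf(x / 1.5) + 0.2
        ws = []
        for seed in range(50):
            noisy = truth + np.random.default_rng(seed).normal(0, 0.05 * 0.5, x.size)
            ws.append(q.fit_esf(x, noisy).w)
        assert np.median(ws) == pytest.approx(1.5, rel=0.05)

    def test_falling_edge_fitted(self):
        x = np.linspace(-5, 5, 100)
        y = -0.7 * erf((x - 0.5) / 0.8) + 1.0
        fit = q.fit_esf(x, y)
        assert fit.w == pytest.approx(0.8, abs=1e-6)
        assert fit.a == pytest.approx(-0.7, abs=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            q.fit_esf(np.arange(5.0), np.arange(5.0))

    def test_unresolved_edge_raises(self):
        x = np.linspace(-1, 1, 30)
        y = 0.5 + 0.5 * x  # linear ramp: w pins at the span
        with pytest.raises(EsfFitError):
            q.fit_esf(x, y)

    def test_lsf_is_gaussian_derivative(self):
        fit = q.ResolutionFit(a=0.8, b=0.1, x0=0.4, w=1.2, residual_norm=0)
        x = np.linspace(-4, 4, 1001)
        numeric = np.gradient(fit.esf(x), x)
        np.testing.assert_allclose(fit.lsf(x), numeric, atol=1e-3)


class TestKnifeEdgePipeline:
    def test_qmc_to_classical_lsf_ratio_is_half(self):
        cfg = q.OpticalConfig(na_effective=0.3, pixel_pitch_um=0.1)
        rc = q.knife_edge_resolution(cfg, "classical").R
        rq = q.knife_edge_resolution(cfg, "qmc").R
        assert rq / rc == pytest.approx(0.5, abs=0.05)

    def test_gaussian_psf_edge_width_closed_form(self):
        cfg = q.OpticalConfig(
            na_effective=0.25, pixel_pitch_um=0.05, psf_model="gaussian"
        )
        fit = q.knife_edge_resolution(cfg, "classical")
        sigma = 0.21 * 0.532 / 0.25
        assert fit.w == pytest.approx(sigma * math.sqrt(2), rel=0.02)

    def test_resolution_vs_z_symmetric_and_halved(self):
        cfg = q.OpticalConfig(
            na_effective=0.25, pixel_pitch_um=0.15, defocus_zr_um=8.0
        )
        table = q.resolution_vs_z(cfg, [-6.0, 0.0, 6.0])
        r = table.set_index("z_um")
        assert r.loc[-6.0, "R_classical_um"] == pytest.approx(
            r.loc[6.0, "R_classical_um"], rel=1e-9
        )
        ratios = (table.R_qmc_um / table.R_classical_um).values
        assert np.all(np.abs(ratios - 0.5) < 0.05)

    def test_calibration_hits_target_classical_resolution(self):
        cal = q.calibrate_na(2.9)
        assert q.knife_edge_resolution(cal, "classical").R == pytest.approx(
            2.9, abs=0.01
        )


class TestSimulationExperiments:
    def _setup(self, shape):
        obj = np.zeros(shape)
        obj[:, : shape[1] // 2] = 1.0
        mo = np.zeros(shape, bool)
        mo[2:-2, 1 : shape[1] // 2 - 2] = True
        mb = np.zeros(shape, bool)
        mb[2:-2, shape[1] // 2 + 2 : -1] = True
        return obj, mo, mb

    def test_cnr_grows_as_sqrt_n(self):
        shape = (12, 12)
        obj, mo, mb = self._setup(shape)
        base = q.default_config(1000, shape, object_map=obj, seed=0)
        table = q.cnr_vs_frames(base, [2000, 8000, 32000], mo, mb, n_repeats=4, seed=2)
        slope = loglog_slope(table.n_frames, table.cnr_mean)
        assert slope == pytest.approx(0.5, abs=0.12)

    def test_same_seed_reproduces_cnr(self):
        shape = (10, 10)
        obj, mo, mb = self._setup(shape)
        base = q.default_config(1000, shape, object_map=obj, seed=0)
        t1 = q.cnr_vs_frames(base, [3000], mo, mb, n_repeats=2, seed=9)
        t2 = q.cnr_vs_frames(base, [3000], mo, mb, n_repeats=2, seed=9)
        assert t1.cnr_mean[0] == t2.cnr_mean[0]

    def test_nonincreasing_frame_grid_rejected(self):
        shape = (10, 10)
        obj, mo, mb = self._setup(shape)
        base = q.default_config(1000, shape, object_map=obj, seed=0)
        with pytest.raises(ValueError):
            q.cnr_vs_frames(base, [2000, 2000], mo, mb)

    def test_single_frame_propagates_covariance_error(self):
        shape = (10, 10)
        obj, mo, mb = self._setup(shape)
        base = q.default_config(1000, shape, object_map=obj, seed=0)
        with pytest.raises(ValueError):
            q.cnr_vs_frames(base, [1], mo, mb, n_repeats=1)

    def test_stray_light_degrades_classical_not_qmc(self):
        shape = (16, 16)
        obj, mo, mb = self._setup(shape)
        base = q.default_config(10_000, shape, object_map=obj, seed=0)
        table = q.cnr_vs_stray(base, [0.0, 8.0], mo, mb, n_repeats=3, seed=5)
        r = table.set_index("stray_ratio")
        # classical collapses under 8x stray speckle; QMC degrades mildly
        assert r.loc[8.0, "classical_cnr_mean"] < 0.2 * r.loc[0.0, "classical_cnr_mean"]
        assert r.loc[8.0, "qmc_cnr_mean"] > 0.2 * r.loc[0.0, "qmc_cnr_mean"]


class TestDisplayInterpolation:
    def test_interpolant_passes_through_samples(self, rng):
        img = rng.random((6, 7))
        fine = display_interpolate(img, factor=3)
        np.testing.assert_allclose(fine[::3, ::3], img, atol=1e-12)

    def test_output_shape(self):
        fine = display_interpolate(np.zeros((5, 4)), factor=4)
        assert fine.shape == (17, 13)
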