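"""STA computation, SVD separation, Gaussian RF fits and derived geometry."""

import numpy as np
import pytest

from rgcsc.receptive_field import (STA, GaussianRF, SpatialRF, compute_sta,
                                   contour_mask, effective_diameter,
                                   fit_gaussian_rf, separate_sta)
from rgcsc.synthetic import StimulusMovie, generate_checkerboard_noise


def _movie(frames, fr=30.0, pitch=30.0):
    return StimulusMovie(frames=frames, frame_rate=fr, pixel_pitch=pitch, square_px=1)


class TestComputeSta:
    def test_single_spike_returns_pre_spike_segment(self, rng):
        frames = rng.integers(0, 2, (30, 4, 4)) * 2 - 1
        movie = _movie(frames)
        t_spike = 25.4 / 30.0  # inside frame 25
        sta = compute_sta(movie, [t_spike], lag_window_ms=660.0)
        assert sta.n_spikes == 1
        for lag in range(20):
            assert np.array_equal(sta.values[lag], frames[25 - lag])

    def test_deterministic_trigger_pixel_peaks_at_lag_zero(self, rng):
        frames = rng.integers(0, 2, (400, 6, 6)) * 2 - 1
        movie = _movie(frames)
        # spike in the middle of every frame where pixel (2, 3) is bright
        trigger = frames[:, 2, 3] == 1
        spikes = (np.nonzero(trigger)[0] + 0.5) / 30.0
        sta = compute_sta(movie, spikes)
        assert sta.values[0, 2, 3] == pytest.approx(1.0)
        assert np.unravel_index(np.argmax(sta.values[0]), (6, 6)) == (2, 3)

    def test_independent_spikes_bounded_by_clt(self):
        movie = generate_checkerboard_noise(3000, 8, 1, seed=3, pixel_pitch=30.0)
        rng = np.random.default_rng(7)
        spikes = np.sort(rng.uniform(0.7, movie.duration_s, 2000))
        sta = compute_sta(movie, spikes)
        assert np.max(np.abs(sta.values)) < 4.0 / np.sqrt(sta.n_spikes)

    def test_no_qualifying_spikes_is_error(self, rng):
        frames = rng.integers(0, 2, (25, 4, 4)) * 2 - 1
        with pytest.raises(ValueError, match="qualifying"):
            compute_sta(_movie(frames), [0.01])


class TestSeparateSta:
    def test_exact_rank_one_recovery(self, rng):
        t = rng.normal(size=20)
        s = rng.normal(size=(8, 9))
        sta = STA(values=t[:, None, None] * s[None], lag_window_ms=660.0,
                  frame_rate=30.0, n_spikes=100)
        spatial, temporal = separate_sta(sta, pixel_pitch=30.0)
        recon = np.outer(temporal.weights, spatial.weights.ravel())
        orig = sta.values.reshape(20, -1)
        scale = np.linalg.norm(orig)
        assert np.linalg.norm(recon * scale - orig * np.sign(
            np.sum(recon * orig))) < 1e-9 * scale
        assert np.linalg.norm(spatial.weights) == pytest.approx(1.0)
        assert np.linalg.norm(temporal.weights) == pytest.approx(1.0)

    def test_matches_brute_force_best_rank_one(self, rng):
        vals = rng.normal(size=(20, 5, 6))
        sta = STA(values=vals, lag_window_ms=660.0, frame_rate=30.0, n_spikes=10)
        spatial, temporal = separate_sta(sta, pixel_pitch=30.0)
        # independent oracle: scan the optimal scaling of the returned pair
        # against the SVD-optimal Frobenius residual of the unfolding
        m = vals.reshape(20, -1)
        sv = np.linalg.svd(m, compute_uv=False)
        best_resid = np.sqrt(np.sum(sv[1:] ** 2))
        coeff = temporal.weights @ m @ spatial.weights.ravel()
        resid = np.linalg.norm(
            m - coeff * np.outer(temporal.weights, spatial.weights.ravel()))
        assert resid == pytest.approx(best_resid, rel=1e-10)

    def test_sign_convention_peak_positive_off_temporal_negative(self, rng):
        t = -np.abs(rng.normal(size=20))  # OFF-like: negative temporal filter
        s = np.abs(rng.normal(size=(6, 6)))
        sta = STA(values=t[:, None, None] * s[None], lag_window_ms=660.0,
                  frame_rate=30.0, n_spikes=50)
        spatial, temporal = separate_sta(sta, pixel_pitch=30.0)
        peak = spatial.weights.flat[np.argmax(np.abs(spatial.weights))]
        assert peak > 0
        assert temporal.weights[np.argmax(np.abs(temporal.weights))] < 0

    def test_zero_sta_is_error(self):
        sta = STA(values=np.zeros((20, 4, 4)), lag_window_ms=660.0,
                  frame_rate=30.0, n_spikes=5)
        with pytest.raises(ValueError):
            separate_sta(sta)


class TestGaussianFit:
    def test_noiseless_recovery(self):
        truth = GaussianRF(mu=[20.0, 12.0], sigma=np.diag([16.0, 4.0]),
                           pixel_pitch=7.5)
        weights = truth.weights((24, 40))
        spatial = SpatialRF(weights=weights / np.linalg.norm(weights), pixel_pitch=7.5)
        fit = fit_gaussian_rf(spatial)
        assert np.all(np.abs(fit.mu - truth.mu) < 0.05)
        assert np.allclose(fit.sigma, truth.sigma, rtol=0.01)
        assert fit.fit_info["converged"]

    def test_noisy_recovery_center(self, rng):
        truth = GaussianRF(mu=[15.0, 17.0], sigma=np.eye(2) * 9.0, pixel_pitch=7.5)
        weights = truth.weights((32, 32))
        errs = []
        for _ in range(5):
            noisy = weights + rng.normal(0, weights.max() / 10, weights.shape)
            fit = fit_gaussian_rf(SpatialRF(
                weights=noisy / np.linalg.norm(noisy), pixel_pitch=7.5))
            errs.append(np.max(np.abs(fit.mu - truth.mu)))
        assert np.median(errs) < 0.5

    def test_negative_peak_map_is_flipped(self):
        truth = GaussianRF(mu=[10.0, 10.0], sigma=np.eye(2) * 4.0, pixel_pitch=7.5)
        weights = -truth.weights((20, 20))
        fit = fit_gaussian_rf(SpatialRF(
            weights=weights / np.linalg.norm(weights), pixel_pitch=7.5))
        assert fit.fit_info["sign_flipped"]
        assert np.all(np.abs(fit.mu - truth.mu) < 0.1)

    def test_constant_map_is_error(self):
        with pytest.raises(ValueError):
            flat = np.full((8, 8), 0.125)
            fit_gaussian_rf(SpatialRF(weights=flat / np.linalg.norm(flat),
                                      pixel_pitch=7.5))


class TestGeometry:
    def test_effective_diameter_circular(self):
        rf = GaussianRF(mu=[0, 0], sigma=np.eye(2) * 25.0, pixel_pitch=7.5)
        assert effective_diameter(rf) == pytest.approx(3 * 5 * 7.5)

    def test_effective_diameter_elliptic_hand_value(self):
        rf = GaussianRF(mu=[0, 0], sigma=np.diag([16.0, 1.0]), pixel_pitch=7.5)
        # full 1.5-sigma axes: a = 3*4, b = 3*1 px -> d = 3*sqrt(4) * 7.5 um
        assert effective_diameter(rf) == pytest.approx(45.0)

    def test_effective_diameter_rotation_invariant(self):
        base = np.diag([16.0, 1.0])
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rf1 = GaussianRF(mu=[0, 0], sigma=base, pixel_pitch=7.5)
        rf2 = GaussianRF(mu=[0, 0], sigma=rot @ base @ rot.T, pixel_pitch=7.5)
        assert effective_diameter(rf1) == pytest.approx(effective_diameter(rf2))

    def test_contour_mask_area_and_nesting(self):
        rf = GaussianRF(mu=[40.0, 40.0], sigma=np.eye(2) * 25.0, pixel_pitch=7.5)
        mask3, n3 = contour_mask(rf, 3.0, (80, 80))
        area = np.pi * 15.0**2
        perimeter = 2 * np.pi * 15.0
        assert abs(n3 - area) <= perimeter
        mask2, n2 = contour_mask(rf, 2.0, (80, 80))
        assert n2 < n3
        assert np.all(mask3[mask2])  # nested

    def test_mask_and_diameter_amplitude_invariant(self, small_images):
        # geometry depends on (mu, sigma) only; rescaling a fitted map's
        # amplitude does not change the normalized RF object
        truth = GaussianRF(mu=[31.5, 31.5], sigma=np.eye(2) * 16.0, pixel_pitch=7.5)
        w = truth.weights((64, 64))
        fits = []
        for scale in (1.0, 7.3):
            sw = w * scale
            fits.append(fit_gaussian_rf(SpatialRF(
                weights=sw / np.linalg.norm(sw), pixel_pitch=7.5)))
        assert effective_diameter(fits[0]) == pytest.approx(
            effective_diameter(fits[1]), rel=1e-6)
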