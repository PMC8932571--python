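"""Generators: images, checkerboard noise, model cells and spike counts."""

import numpy as np
import pytest

from rgcsc.image_features import ContrastImage
from rgcsc.receptive_field import contour_mask
from rgcsc.synthetic import (NoiseSpec, SyntheticImageSetSpec, cell_drive,
                             draw_counts, expected_counts,
                             generate_checkerboard_noise, generate_images,
                             make_linear_cell, make_subunit_cell,
                             simulate_flash_responses,
                             simulate_white_noise_spikes, _softplus)


class TestImages:
    def test_sd_near_target_and_determinism(self):
        spec = SyntheticImageSetSpec(n_images=6, size_px=64, seed=9)
        imgs = generate_images(spec)
        sds = [im.values.std() for im in imgs]
        # clipping removes some variance below the 0.5 target; the
        # heavy-tailed modulated ensemble clips more on a small canvas
        assert 0.35 < np.mean(sds) <= 0.5
        again = generate_images(spec)
        for a, b in zip(imgs, again):
            assert np.array_equal(a.values, b.values)

    def test_mean_contrast_near_zero(self):
        spec = SyntheticImageSetSpec(n_images=4, size_px=64, seed=2)
        for im in generate_images(spec):
            assert abs(im.values.mean()) < 0.05

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticImageSetSpec(n_images=1)
        with pytest.raises(ValueError):
            SyntheticImageSetSpec(target_sd_fraction=0.0)

    def test_white_spectrum_images_unclipped_sd(self):
        spec = SyntheticImageSetSpec(n_images=3, size_px=64, seed=4,
                                     spectral_exponent=0.0,
                                     contrast_modulation=0.0)
        for im in generate_images(spec):
            # Gaussian image clipped at +/-2 SD retains ~96% of the SD
            assert im.values.std() == pytest.approx(0.48, abs=0.02)


class TestCheckerboard:
    def test_square_structure_and_mean(self):
        movie = generate_checkerboard_noise(1000, 16, 4, seed=1)
        assert set(np.unique(movie.frames)) == {-1, 1}
        # each 4x4 square is spatially constant
        sq = movie.frames[:, :4, :4]
        assert np.all(sq == sq[:, :1, :1])
        # per-square mean over frames ~ Binomial CI around 0
        means = movie.frames[:, ::4, ::4].mean(axis=0)
        assert np.all(np.abs(means) < 4 / np.sqrt(1000))

    def test_full_field_flicker_degenerate_case(self):
        movie = generate_checkerboard_noise(50, 8, 8, seed=0)
        for frame in movie.frames:
            assert np.ptp(frame) == 0  # one square covers the grid

    def test_determinism_and_divisibility(self):
        a = generate_checkerboard_noise(20, 12, 3, seed=5)
        b = generate_checkerboard_noise(20, 12, 3, seed=5)
        assert np.array_equal(a.frames, b.frames)
        with pytest.raises(ValueError):
            generate_checkerboard_noise(10, 10, 3, seed=0)


class TestNoise:
    def test_thinned_fano_calibrated(self, rng):
        c = draw_counts(np.full(10000, 5.0), NoiseSpec(target_fano=0.3), rng)
        assert c.mean() == pytest.approx(5.0, abs=0.1)
        assert c.var(ddof=1) / c.mean() == pytest.approx(0.3, abs=0.05)

    def test_poisson_and_deterministic_controls(self, rng):
        c = draw_counts(np.full(10000, 5.0), NoiseSpec(family="poisson"), rng)
        assert c.var(ddof=1) / c.mean() == pytest.approx(1.0, abs=0.05)
        d = draw_counts(np.array([1.2, 3.7]), NoiseSpec(family="deterministic"), rng)
        assert np.array_equal(d, [1, 4])

    def test_invalid_family_and_fano(self):
        with pytest.raises(ValueError):
            NoiseSpec(family="gamma")
        with pytest.raises(ValueError):
            NoiseSpec(target_fano=1.5)


class TestFlashResponses:
    def test_linear_off_uniform_contrast_closed_form(self, uniform_image):
        cell = make_linear_cell(center_px=(31.5, 31.5), sigma_um=60.0,
                                noise=NoiseSpec(family="deterministic"))
        img = uniform_image(-0.5)
        # closed form: I_mean = -0.5 * mean(G) on the mask; OFF flips sign
        mask, _ = contour_mask(cell.rf, 3.0, img.shape)
        g_mean = cell.rf.weights(img.shape)[mask].mean()
        a1, a2, a3 = cell.output_params
        expected = round(float(_softplus(0.5 * g_mean, a1, a2, a3)))
        resp = simulate_flash_responses(cell, [img], n_trials=3, seed=0)
        assert np.all(resp.counts == expected)

    def test_zero_contrast_low_offset_gives_near_zero(self, uniform_image):
        cell = make_linear_cell(center_px=(31.5, 31.5), sigma_um=60.0,
                                output_params=(2.5, 80.0, -0.5),
                                noise=NoiseSpec(family="deterministic"))
        resp = simulate_flash_responses(cell, [uniform_image(0.0)], 2, seed=0)
        assert np.all(resp.counts == 0)

    def test_poisson_many_trials_fano_near_one(self, small_images):
        cell = make_linear_cell(center_px=(31.5, 31.5), sigma_um=60.0,
                                noise=NoiseSpec(family="poisson"))
        resp = simulate_flash_responses(cell, small_images[:3], 4000, seed=1)
        ff = resp.var_counts / resp.mean_counts
        assert np.allclose(ff, 1.0, atol=0.1)

    def test_determinism_and_trial_validation(self, small_images):
        cell = make_linear_cell(center_px=(31.5, 31.5), sigma_um=60.0)
        a = simulate_flash_responses(cell, small_images[:3], 5, seed=42)
        b = simulate_flash_responses(cell, small_images[:3], 5, seed=42)
        assert np.array_equal(a.counts, b.counts)
        with pytest.raises(ValueError):
            simulate_flash_responses(cell, small_images[:3], 0, seed=1)


class TestSpatialLinearity:
    def test_split_field_reversal_distinguishes_cell_kinds(self):
        # contrast-reversing half-field pair: a linear cell's summed drive
        # equals twice the gray response; a rectified-subunit cell's exceeds it
        size = 128
        left = np.zeros((size, size))
        left[:, : size // 2] = 0.6
        left[:, size // 2:] = -0.6
        img_a = ContrastImage(values=left, pixel_pitch=7.5)
        img_b = ContrastImage(values=-left, pixel_pitch=7.5)
        lin = make_linear_cell()
        sub = make_subunit_cell()
        lin_sum = cell_drive(lin, img_a) + cell_drive(lin, img_b)
        assert lin_sum == pytest.approx(0.0, abs=1e-12)
        sub_sum = cell_drive(sub, img_a) + cell_drive(sub, img_b)
        assert sub_sum > 0.1  # rectified halves do not cancel


class TestWhiteNoiseSpikes:
    def test_zero_gain_gives_empty_spike_list(self):
        movie = generate_checkerboard_noise(100, 16, 1, seed=0, pixel_pitch=30.0)
        cell = make_linear_cell(center_px=(7.5, 7.5), sigma_um=60.0,
                                pixel_pitch=30.0, output_params=(0.0, 80.0, 0.0))
        assert simulate_white_noise_spikes(cell, movie, seed=1).size == 0

    def test_spikes_sorted_within_duration_and_deterministic(self):
        movie = generate_checkerboard_noise(2000, 16, 1, seed=0, pixel_pitch=30.0)
        cell = make_linear_cell(center_px=(7.5, 7.5), sigma_um=60.0,
                                pixel_pitch=30.0)
        s1 = simulate_white_noise_spikes(cell, movie, seed=3)
        s2 = simulate_white_noise_spikes(cell, movie, seed=3)
        assert np.array_equal(s1, s2)
        assert s1.size > 50
        assert np.all(np.diff(s1) >= 0)
        assert s1[0] >= 0 and s1[-1] <= movie.duration_s


class TestCellValidation:
    def test_subunit_fields_required_iff_subunit(self):
        with pytest.raises(ValueError):
            make_linear_cell().__class__(
                polarity="OFF", rf=make_linear_cell().rf, kind="subunit")
        cell = make_subunit_cell()
        assert cell.subunit_sigma_um == pytest.approx(20.0)  # 60 um / 3
        assert cell.subunit_spacing_um == pytest.approx(cell.subunit_sigma_um)

    def test_expected_counts_nonnegative(self, small_images):
        for cell in (make_linear_cell(center_px=(31.5, 31.5), sigma_um=60.0),
                     make_subunit_cell(center_px=(31.5, 31.5), sigma_um=60.0)):
            mu = expected_counts(cell, small_images[:5])
            assert np.all(mu >= 0)
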