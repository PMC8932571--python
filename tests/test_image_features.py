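"""Weber contrast, standardization, and the I_mean / LSC statistics."""

import numpy as np
import pytest
from scipy.stats import norm

from rgcsc.image_features import (ContrastImage, compute_imean, compute_lsc,
                                  feature_table, smooth_image,
                                  standardize_contrast, to_weber_contrast)
from rgcsc.receptive_field import GaussianRF, contour_mask


def naive_imean(image, rf, n_sigma=3.0):
    """Independent double-loop oracle for the weighted mean statistic."""
    ny, nx = image.shape
    prec = np.linalg.inv(rf.sigma)
    vals = []
    for y in range(ny):
        for x in range(nx):
            d = np.array([x - rf.mu[0], y - rf.mu[1]])
            m2 = d @ prec @ d
            if m2 <= n_sigma**2:
                vals.append(np.exp(-0.5 * m2) * image.values[y, x])
    return np.mean(vals), vals


def test_weber_contrast_endpoints():
    lum = np.array([[10.0, 20.0, 0.0]])
    c = to_weber_contrast(lum, l_mean=10.0)
    assert np.allclose(c.values, [[0.0, 1.0, -1.0]])
    with pytest.raises(ValueError):
        to_weber_contrast(lum, l_mean=0.0)


def test_standardize_contrast_moments_and_clipping(rng):
    img = rng.normal(100.0, 25.0, (128, 128))
    out, clip_frac = standardize_contrast(img, target_sd=0.5)
    assert abs(out.values.mean()) < 0.05  # clipping shifts the mean slightly
    # Gaussian image: contrast beyond +/-1 is the +/-2 SD tail
    assert clip_frac == pytest.approx(2 * norm.cdf(-2.0), abs=0.01)
    assert out.values.min() >= -1.0 and out.values.max() <= 1.0
    with pytest.raises(ValueError):
        standardize_contrast(np.ones((8, 8)))


def test_standardize_prec_clip_mean_is_zero(rng):
    # with no clipping active the mean is zero to machine precision
    img = rng.uniform(90, 110, (64, 64))
    out, clip_frac = standardize_contrast(img, target_sd=0.2)
    assert clip_frac == 0.0
    assert abs(out.values.mean()) < 1e-12
    assert out.values.std() == pytest.approx(0.2, rel=1e-9)


def test_standardize_gray_rgb_matches_single_channel(rng):
    gray = rng.uniform(0, 1, (32, 32))
    rgbgray = np.repeat(gray[:, :, None], 3, axis=2)
    a, _ = standardize_contrast(gray)
    b, _ = standardize_contrast(rgbgray)
    assert np.allclose(a.values, b.values)


def test_imean_flat_weight_limit(uniform_image):
    # huge sigma: G ~ 1 on a small mask, so I_mean ~ the uniform contrast
    rf = GaussianRF(mu=[31.5, 31.5], sigma=np.eye(2) * 1e8, pixel_pitch=7.5)
    img = uniform_image(-0.5)
    assert compute_imean(img, rf) == pytest.approx(-0.5, rel=1e-4)
    assert compute_lsc(img, rf) == pytest.approx(0.0, abs=1e-5)


def test_imean_hand_example():
    # 4 relevant pixels with G = (1, .5, .5, .25) and C = (1, -1, 1, -1):
    # the statistic is an average of G*C over the mask
    g = np.array([1.0, 0.5, 0.5, 0.25])
    c = np.array([1.0, -1.0, 1.0, -1.0])
    assert np.mean(g * c) == pytest.approx(0.1875)


def test_lsc_two_pixel_hand_value():
    # G = 1 on both pixels, C = +/-0.4 -> sample SD = sqrt(0.32)
    w = np.array([0.4, -0.4])
    assert np.std(w, ddof=1) == pytest.approx(np.sqrt(0.32))


def test_statistics_match_naive_oracle(small_images, circular_rf):
    for img in small_images[:6]:
        expected, vals = naive_imean(img, circular_rf)
        assert compute_imean(img, circular_rf) == pytest.approx(expected, abs=1e-10)
        assert compute_lsc(img, circular_rf) == pytest.approx(
            np.std(vals, ddof=1), abs=1e-10)


def test_imean_linear_lsc_homogeneous(small_images, circular_rf):
    a, b = small_images[0], small_images[1]
    mix = ContrastImage(values=0.3 * a.values + 0.7 * b.values, pixel_pitch=a.pixel_pitch)
    assert compute_imean(mix, circular_rf) == pytest.approx(
        0.3 * compute_imean(a, circular_rf) + 0.7 * compute_imean(b, circular_rf),
        abs=1e-12)
    scaled = ContrastImage(values=-2.0 * a.values, pixel_pitch=a.pixel_pitch)
    assert compute_lsc(scaled, circular_rf) == pytest.approx(
        2.0 * compute_lsc(a, circular_rf), rel=1e-12)


def test_lsc_weighted_original_variant_close(small_images, circular_rf):
    img = small_images[0]
    default = compute_lsc(img, circular_rf)
    alt = compute_lsc(img, circular_rf, weighted_original=True)
    assert alt > 0 and default > 0  # both well-defined; related but distinct


def test_smooth_image_contracts_variance(rng):
    img = ContrastImage(values=rng.normal(0, 0.5, (64, 64)), pixel_pitch=7.5)
    variances = [smooth_image(img, s).values.var() for s in (0.0, 15.0, 45.0, 90.0)]
    assert np.all(np.diff(variances) < 0)
    assert np.array_equal(smooth_image(img, 0.0).values, img.values)
    const = ContrastImage(values=np.full((32, 32), 0.3), pixel_pitch=7.5)
    assert np.allclose(smooth_image(const, 60.0).values, 0.3, atol=1e-7)


def test_feature_table_scale_zero_matches_direct(small_images, circular_rf):
    table = feature_table(small_images, circular_rf, smoothing_scale_um=0.0)
    assert len(table) == len(small_images)
    for i in (0, 7, 19):
        assert table.loc[i, "i_mean"] == pytest.approx(
            compute_imean(small_images[i], circular_rf))
        assert table.loc[i, "lsc"] == pytest.approx(
            compute_lsc(small_images[i], circular_rf))


def test_feature_table_smoothing_reduces_lsc(small_images, circular_rf):
    t0 = feature_table(small_images, circular_rf, smoothing_scale_um=0.0)
    t1 = feature_table(small_images, circular_rf, smoothing_scale_um=300.0)
    # I_mean always comes from the unsmoothed image
    assert np.allclose(t0["i_mean"], t1["i_mean"])
    assert (t1["lsc"] < t0["lsc"]).all()


def test_imean_lsc_coupling_positive(small_images, circular_rf):
    # natural-like ensembles couple local contrast to |mean intensity|
    t = feature_table(small_images, circular_rf)
    r = np.corrcoef(np.abs(t["i_mean"]), t["lsc"])[0, 1]
    assert r > 0


def test_empty_mask_is_error(uniform_image):
    rf = GaussianRF(mu=[500.0, 500.0], sigma=np.eye(2) * 4.0, pixel_pitch=7.5)
    with pytest.raises(ValueError):
        compute_imean(uniform_image(0.1), rf)
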