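"""Weber-contrast images and the two local stimulus statistics.

A flashed image, seen through a cell's fitted Gaussian receptive field,
is summarized by two numbers:

* ``I_mean`` — the mean of the RF-weighted pixel contrasts inside the
  3-sigma contour.  This is the drive of the classical LN model.
* ``LSC`` (local spatial contrast) — the sample standard deviation of the
  same weighted pixel contrasts.  A purely spatial, second-order statistic
  that a linear model is blind to.

Both use the peak-normalized kernel G (A=1, B=0) of
:class:`~rgcsc.receptive_field.GaussianRF` and the set of N pixels whose
centers fall within the 3-sigma Mahalanobis contour:

    I_mean = (1/N)      sum_i G(x_i) C(x_i)
    LSC    = sqrt( (1/(N-1)) sum_i (G(x_i) C(x_i) - I_mean)^2 )
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .receptive_field import GaussianRF, contour_mask

__all__ = [
    "ContrastImage",
    "RGB_WEIGHTS",
    "to_weber_contrast",
    "standardize_contrast",
    "compute_imean",
    "compute_lsc",
    "smooth_image",
    "feature_table",
]

#: Grayscale conversion weights, ratio R:G:B = 30:59:11.
RGB_WEIGHTS = np.array([0.30, 0.59, 0.11])


@dataclass
class ContrastImage:
    """2D grid of Weber contrast values with physical pixel pitch (um/px)."""

    values: np.ndarray
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("contrast image must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("contrast image contains non-finite values")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def to_weber_contrast(luminance: np.ndarray, l_mean: float, pixel_pitch: float = 1.0) -> ContrastImage:
    """Pixel-wise Weber contrast C = (L - L_mean) / L_mean."""
    if l_mean <= 0:
        raise ValueError("mean luminance must be positive")
    lum = np.asarray(luminance, dtype=float)
    return ContrastImage(values=(lum - l_mean) / l_mean, pixel_pitch=pixel_pitch)


def standardize_contrast(
    image: np.ndarray,
    target_sd: float = 0.5,
    clip: tuple[float, float] = (-1.0, 1.0),
    pixel_pitch: float = 1.0,
) -> tuple[ContrastImage, float]:
    """Shift/scale an image to zero-mean contrast with a fixed SD, then clip.

    Mirrors display preparation for flashed stimuli: the mean pixel
    intensity is mapped to the background (contrast 0), the contrast SD is
    set to ``target_sd`` (intensity SD as a fraction of the mean), and
    contrast is clipped to ``clip`` — the luminance range of the display
    (0% to 200% of the mean corresponds to contrast -1..+1).  Color images
    are first converted to grayscale with R:G:B weights 30:59:11.

    Returns the standardized :class:`ContrastImage` and the fraction of
    pixels that were clipped.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        if img.shape[2] != 3:
            raise ValueError("color images must have 3 channels")
        img = img @ RGB_WEIGHTS
    if img.ndim != 2:
        raise ValueError("image must be 2D grayscale or HxWx3 color")
    sd = img.std()
    if sd == 0:
        raise ValueError("constant image cannot be standardized")
    c = (img - img.mean()) / sd * target_sd
    lo, hi = clip
    clipped = (c < lo) | (c > hi)
    c = np.clip(c, lo, hi)
    return ContrastImage(values=c, pixel_pitch=pixel_pitch), float(clipped.mean())


def _masked_weighted(image: ContrastImage, rf: GaussianRF, n_sigma: float) -> np.ndarray:
    mask, n = contour_mask(rf, n_sigma, image.shape)
    if n == 0:
        raise ValueError("receptive-field contour does not overlap the image")
    g = rf.weights(image.shape)
    return g[mask] * image.values[mask]


def compute_imean(image: ContrastImage, rf: GaussianRF, n_sigma: float = 3.0) -> float:
    """RF-weighted mean contrast over the n-sigma contour (LN-model drive)."""
    return float(_masked_weighted(image, rf, n_sigma).mean())


def compute_lsc(
    image: ContrastImage,
    rf: GaussianRF,
    n_sigma: float = 3.0,
    weighted_original: bool = False,
) -> float:
    """Local spatial contrast over the n-sigma contour.

    Default: sample SD (denominator N-1) of the weighted pixel values
    G(x_i)*C(x_i).  With ``weighted_original=True`` the G-weighted SD of
    the raw contrasts is used instead (a closely related alternative;
    the difference between the two measures is small).
    """
    mask, n = contour_mask(rf, n_sigma, image.shape)
    if n < 2:
        raise ValueError("LSC needs at least two pixels inside the contour")
    g = rf.weights(image.shape)[mask]
    c = image.values[mask]
    if weighted_original:
        m = float(np.sum(g * c) / np.sum(g))
        return float(np.sqrt(np.sum(g * (c - m) ** 2) / np.sum(g)))
    w = g * c
    return float(np.std(w, ddof=1))


def smooth_image(image: ContrastImage, spatial_scale_um: float) -> ContrastImage:
    """Blur with a circular Gaussian; the scale is 3x the Gaussian SD.

    The spatial-scale convention matches the effective-diameter convention
    for receptive fields, so a smoothing scale is directly comparable to
    an RF or subunit diameter.  Scale 0 returns the image unchanged.
    Boundaries are handled by reflective padding.
    """
    if spatial_scale_um < 0:
        raise ValueError("spatial scale must be nonnegative")
    if spatial_scale_um == 0:
        return ContrastImage(values=image.values.copy(), pixel_pitch=image.pixel_pitch)
    sigma_px = spatial_scale_um / 3.0 / image.pixel_pitch
    return ContrastImage(
        values=gaussian_filter(image.values, sigma=sigma_px, mode="reflect"),
        pixel_pitch=image.pixel_pitch,
    )


def feature_table(
    images,
    rf: GaussianRF,
    smoothing_scale_um: float = 0.0,
    n_sigma: float = 3.0,
) -> pd.DataFrame:
    """Per-image I_mean and LSC as a DataFrame.

    ``I_mean`` is always taken from the unsmoothed image; ``LSC`` is taken
    from the image smoothed at ``smoothing_scale_um``, so the spatial scale
    affects only the contrast statistic.
    """
    images = list(images)
    if not images:
        return pd.DataFrame(columns=["image_id", "i_mean", "lsc", "smoothing_scale_um"])
    shape = images[0].shape
    # kernel and mask depend only on the RF and grid: compute them once
    mask, n = contour_mask(rf, n_sigma, shape)
    if n < 2:
        raise ValueError("receptive-field contour covers fewer than 2 pixels")
    g_masked = rf.weights(shape)[mask]
    rows = []
    for i, img in enumerate(images):
        if img.shape != shape:
            raise ValueError("all images must share one grid")
        w = g_masked * img.values[mask]
        ws = g_masked * smooth_image(img, smoothing_scale_um).values[mask]
        rows.append(
            {
                "image_id": i,
                "i_mean": float(w.mean()),
                "lsc": float(np.std(ws, ddof=1)),
                "smoothing_scale_um": smoothing_scale_um,
            }
        )
    return pd.DataFrame(rows)
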