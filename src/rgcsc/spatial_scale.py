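"""Spatial-scale analysis: which smoothing scale maximizes SC performance.

The local spatial contrast is recomputed from progressively blurred
copies of each image (I_mean always comes from the original), the SC
model is refit at every smoothing scale, and the held-out R^2 traces out
an improvement-vs-scale curve.  Smoothing below the subunit scale
averages out contrast variation that the subunits themselves pool over
and helps the prediction; smoothing beyond the subunit scale destroys
informative contrast structure and hurts it — so the curve is concave
with an interior maximum near the subunit size.  The optimum is read off
by a second-order polynomial through the maximum point and its two
neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import encoding
from .image_features import feature_table
from .receptive_field import GaussianRF

__all__ = ["ScaleCurve", "OptimalScale", "scale_sweep", "optimal_scale", "DEFAULT_SCALES_UM"]

#: Default smoothing-scale grid in micrometers (0 = no smoothing).
DEFAULT_SCALES_UM = tuple(float(s) for s in range(0, 196, 15))


@dataclass
class ScaleCurve:
    """SC-model performance as a function of the LSC smoothing scale."""

    scales_um: np.ndarray
    r2: np.ndarray
    r2_ln: float
    failed: np.ndarray  # per-scale flag for propagated fit errors

    def __post_init__(self) -> None:
        self.scales_um = np.asarray(self.scales_um, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        self.failed = np.asarray(self.failed, dtype=bool)
        if not (len(self.scales_um) == len(self.r2) == len(self.failed)):
            raise ValueError("curve fields must have equal length")
        if np.any(np.diff(self.scales_um) <= 0):
            raise ValueError("scales must be strictly increasing")

    @property
    def improvement(self) -> np.ndarray:
        """R^2(scale) / R^2 of the LN baseline."""
        return self.r2 / self.r2_ln

    @property
    def normalized_improvement(self) -> np.ndarray:
        """Improvement divided by the improvement with no smoothing."""
        if self.scales_um[0] != 0:
            raise ValueError("normalization requires scale 0 in the grid")
        return self.improvement / self.improvement[0]


def scale_sweep(
    images,
    rf: GaussianRF,
    mean_counts,
    scales_um=DEFAULT_SCALES_UM,
    seed: int | None = 0,
    n_restarts: int = 20,
    train_fraction: float = 0.5,
    drive_sign: float = 1.0,
    max_alternations: int = 500,
) -> ScaleCurve:
    """Refit the SC model with LSC computed at each smoothing scale.

    The train/test split and the LN baseline (which only sees the
    scale-independent I_mean) are computed once; per-scale fit failures
    are flagged and leave a NaN gap rather than aborting the sweep.

    ``drive_sign`` is -1 for OFF cells: the monotone-increasing softplus
    is fit on the polarity-signed mean intensity (the temporal-filter
    convention makes an OFF cell's drive positive for dark stimuli).
    LSC is unaffected by the sign.
    """
    scales = np.asarray(scales_um, dtype=float)
    if np.any(scales < 0):
        raise ValueError("scales must be nonnegative")
    y = np.asarray(mean_counts, dtype=float)
    n = len(images)
    if y.size != n:
        raise ValueError("mean_counts must align with images")
    train, test = encoding.split_train_test(n, fraction=train_fraction, seed=seed)

    base = feature_table(images, rf, smoothing_scale_um=0.0)
    i_mean = drive_sign * base["i_mean"].to_numpy()
    ln = encoding.fit_ln(i_mean[train], y[train], n_restarts=n_restarts, seed=seed)
    ev_ln = encoding.evaluate(ln.predict(i_mean[test]), y[test])

    r2 = np.full(scales.size, np.nan)
    failed = np.zeros(scales.size, dtype=bool)
    warm = None  # previous scale's solution seeds the next fit
    for k, scale in enumerate(scales):
        try:
            feats = feature_table(images, rf, smoothing_scale_um=float(scale))
            lsc = feats["lsc"].to_numpy()
            sc = encoding.fit_sc(i_mean[train], lsc[train], y[train],
                                 n_restarts=n_restarts, seed=seed,
                                 max_alternations=max_alternations,
                                 extra_inits=[warm] if warm else None)
            ev = encoding.evaluate(sc.predict(i_mean[test], lsc[test]), y[test])
            r2[k] = ev.r2
            warm = (sc.a1, sc.a2, sc.a3, sc.w)
        except ValueError:
            failed[k] = True
    return ScaleCurve(scales_um=scales, r2=r2, r2_ln=ev_ln.r2, failed=failed)


@dataclass
class OptimalScale:
    """Interpolated optimum of a scale curve."""

    scale_um: float
    boundary: bool  # True when the maximum sits on the grid edge (no vertex)


def optimal_scale(curve: ScaleCurve) -> OptimalScale:
    """Quadratic interpolation of the R^2 maximum on the scale grid.

    A parabola is fit exactly through the maximum grid point and its two
    neighbors; its vertex is returned if it is a true interior maximum
    (negative curvature, vertex within the neighbor interval).  Otherwise
    the maximum grid point itself is returned with the boundary flag set;
    no extrapolation beyond the grid is attempted.
    """
    ok = ~curve.failed & np.isfinite(curve.r2)
    if ok.sum() < 3:
        raise ValueError("need at least 3 valid scale points")
    scales = curve.scales_um[ok]
    r2 = curve.r2[ok]
    k = int(np.argmax(r2))
    if k == 0 or k == len(scales) - 1:
        return OptimalScale(scale_um=float(scales[k]), boundary=True)
    x = scales[k - 1: k + 2]
    y = r2[k - 1: k + 2]
    c2, c1, _ = np.polyfit(x, y, 2)
    if c2 < 0:
        vertex = -c1 / (2.0 * c2)
        if x[0] <= vertex <= x[2]:
            return OptimalScale(scale_um=float(vertex), boundary=False)
    return OptimalScale(scale_um=float(scales[k]), boundary=True)
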