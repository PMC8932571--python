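"""Receptive-field estimation from white-noise responses.

The pipeline is the classical reverse-correlation chain: spike-triggered
average (STA) of the checkerboard stimulus, rank-1 separation of the STA
into a spatial map and a temporal filter by singular value decomposition,
and a least-squares fit of a two-dimensional Gaussian to the spatial map.
The fitted Gaussian is the receptive-field (RF) model used by all
downstream image statistics: its peak-normalized kernel

    G(x) = exp(-1/2 (x - mu)^T Sigma^{-1} (x - mu))

weights pixel contrasts, and its 3-sigma Mahalanobis contour delimits the
pixels that enter the weighted statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "STA",
    "SpatialRF",
    "TemporalFilter",
    "GaussianRF",
    "compute_sta",
    "separate_sta",
    "fit_gaussian_rf",
    "effective_diameter",
    "contour_mask",
]


@dataclass
class STA:
    """Spike-triggered average: mean pre-spike stimulus segment.

    ``values`` has shape (n_lags, ny, nx); lag 0 is the frame in which the
    spike occurred, increasing lags reach further back in time.
    """

    values: np.ndarray
    lag_window_ms: float
    frame_rate: float
    n_spikes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = int(np.ceil(self.lag_window_ms * self.frame_rate / 1000.0))
        if self.values.shape[0] != expected:
            raise ValueError(
                f"lag axis has {self.values.shape[0]} frames, expected {expected} "
                f"for a {self.lag_window_ms} ms window at {self.frame_rate} Hz"
            )
        if self.n_spikes < 1:
            raise ValueError("STA requires at least one spike")


@dataclass
class SpatialRF:
    """Unit-norm spatial receptive-field map on the stimulus pixel grid."""

    weights: np.ndarray
    pixel_pitch: float  # micrometers per pixel

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        nrm = np.linalg.norm(self.weights)
        if not np.isclose(nrm, 1.0, atol=1e-9):
            raise ValueError(f"spatial weights must have unit Euclidean norm, got {nrm}")


@dataclass
class TemporalFilter:
    """Unit-norm temporal filter over time lags (lag 0 = spike frame)."""

    weights: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        nrm = np.linalg.norm(self.weights)
        if not np.isclose(nrm, 1.0, atol=1e-9):
            raise ValueError(f"temporal weights must have unit Euclidean norm, got {nrm}")


@dataclass
class GaussianRF:
    """Fitted 2D Gaussian receptive field, normalized to A=1, B=0.

    ``mu`` is the center (x, y) in 0-based pixel-center coordinates
    (x = column, y = row); ``sigma`` is the 2x2 covariance in pixel^2.
    The kernel used for image weighting is peak-normalized:
    G(x) = exp(-1/2 (x-mu)^T Sigma^{-1} (x-mu)).
    """

    mu: np.ndarray
    sigma: np.ndarray
    pixel_pitch: float  # micrometers per pixel
    fit_info: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(2)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(2, 2)
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(self.sigma) <= 0):
            raise ValueError("sigma must be positive definite")

    def mahalanobis_sq(self, shape: tuple[int, int]) -> np.ndarray:
        """Squared Mahalanobis distance of every pixel center on a grid."""
        ny, nx = shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        d = np.stack([xx - self.mu[0], yy - self.mu[1]], axis=-1)
        prec = np.linalg.inv(self.sigma)
        return np.einsum("...i,ij,...j->...", d, prec, d)

    def weights(self, shape: tuple[int, int]) -> np.ndarray:
        """Peak-normalized Gaussian kernel evaluated at pixel centers."""
        return np.exp(-0.5 * self.mahalanobis_sq(shape))


def compute_sta(movie, spikes, lag_window_ms: float = 660.0) -> STA:
    """Average the ``lag_window_ms`` of stimulus preceding each spike.

    A spike is assigned to the last stimulus frame whose onset precedes
    (or coincides with) the spike time.  Spikes earlier than one full lag
    window after movie onset, or after the movie end, do not qualify.
    """
    frames = np.asarray(movie.frames)
    spikes = np.asarray(spikes, dtype=float)
    fr = movie.frame_rate
    n_frames = frames.shape[0]
    n_lags = int(np.ceil(lag_window_ms * fr / 1000.0))
    if n_frames < n_lags:
        raise ValueError("movie shorter than the requested lag window")

    frame_idx = np.floor(spikes * fr).astype(int)
    ok = (frame_idx >= n_lags - 1) & (frame_idx < n_frames)
    n_spk = int(ok.sum())
    if n_spk == 0:
        raise ValueError(
            f"no qualifying spikes: {spikes.size} supplied, 0 fall at least "
            f"{lag_window_ms} ms after movie onset and before movie end"
        )
    counts = np.bincount(frame_idx[ok], minlength=n_frames).astype(np.float64)

    sta = np.empty((n_lags,) + frames.shape[1:], dtype=float)
    c = counts[n_lags - 1:]
    for lag in range(n_lags):
        seg = frames[n_lags - 1 - lag: n_frames - lag]
        sta[lag] = np.tensordot(c, seg, axes=(0, 0)) / n_spk
    return STA(values=sta, lag_window_ms=lag_window_ms, frame_rate=fr, n_spikes=n_spk)


def separate_sta(sta: STA, pixel_pitch: float | None = None) -> tuple[SpatialRF, TemporalFilter]:
    """Rank-1 space-time separation of the STA via SVD.

    Returns the leading singular pair of the (lags x pixels) unfolding,
    each normalized to unit Euclidean norm.  Sign convention: the spatial
    factor's peak-magnitude pixel is positive, so the temporal filter
    carries the cell's polarity (OFF cells get a negative temporal peak).
    """
    vals = sta.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("STA contains non-finite values")
    if not np.any(vals):
        raise ValueError("STA is identically zero; cannot separate")
    n_lags = vals.shape[0]
    mat = vals.reshape(n_lags, -1)
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    temporal = u[:, 0]
    spatial = vt[0].reshape(vals.shape[1:])
    peak = spatial.flat[np.argmax(np.abs(spatial))]
    if peak < 0:
        spatial = -spatial
        temporal = -temporal
    pitch = getattr(sta, "pixel_pitch", None) if pixel_pitch is None else pixel_pitch
    if pitch is None:
        pitch = 1.0
    return (
        SpatialRF(weights=spatial, pixel_pitch=pitch),
        TemporalFilter(weights=temporal, frame_rate=sta.frame_rate),
    )


def _gauss_model(params: np.ndarray, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    amp, mx, my, log_l11, l21, log_l22 = params[:6]
    off = params[6]
    l11 = np.exp(log_l11)
    l22 = np.exp(log_l22)
    # Sigma = L L^T with L = [[l11, 0], [l21, l22]]; invert via the factor.
    dx = xx - mx
    dy = yy - my
    # Solve L z = d  =>  z1 = dx/l11, z2 = (dy - l21 z1)/l22; maha^2 = |z|^2
    z1 = dx / l11
    z2 = (dy - l21 * z1) / l22
    return amp * np.exp(-0.5 * (z1**2 + z2**2)) + off


def fit_gaussian_rf(spatial_rf: SpatialRF) -> GaussianRF:
    """Least-squares fit of a 2D Gaussian (A, mu, Sigma, B) to a spatial map.

    The covariance is parameterized through its Cholesky factor (log
    diagonal) so Sigma stays positive definite throughout the
    optimization.  The returned object is normalized to A=1, B=0; the raw
    amplitude, offset, residual and convergence status are kept in
    ``fit_info``.
    """
    data = np.asarray(spatial_rf.weights, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("spatial map contains non-finite values")
    if np.ptp(data) == 0:
        raise ValueError("spatial map is constant; Gaussian fit is undefined")
    ny, nx = data.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)

    flipped = False
    peak_val = data.flat[np.argmax(np.abs(data))]
    if peak_val < 0:  # fit on a positive-peak map; record the flip
        data = -data
        flipped = True

    baseline = np.median(data)
    iy, ix = np.unravel_index(np.argmax(data), data.shape)
    amp0 = data[iy, ix] - baseline
    # moment-based width initialization on the positive part
    pos = np.clip(data - baseline, 0, None)
    tot = pos.sum()
    mx0, my0 = float(ix), float(iy)
    if tot > 0:
        mx0 = float((pos * xx).sum() / tot)
        my0 = float((pos * yy).sum() / tot)
        vx = float((pos * (xx - mx0) ** 2).sum() / tot)
        vy = float((pos * (yy - my0) ** 2).sum() / tot)
    else:
        vx = vy = 1.0
    vx = max(vx, 0.25)
    vy = max(vy, 0.25)
    x0 = np.array([amp0, mx0, my0, 0.5 * np.log(vx), 0.0, 0.5 * np.log(vy), baseline])

    def resid(p):
        return (_gauss_model(p, xx, yy) - data).ravel()

    sol = least_squares(resid, x0, method="lm", max_nfev=20000)
    amp, mx, my, log_l11, l21, log_l22, off = sol.x
    l11 = np.exp(log_l11)
    l22 = np.exp(log_l22)
    chol = np.array([[l11, 0.0], [l21, l22]])
    sigma = chol @ chol.T
    info = {
        "amplitude": float(-amp if flipped else amp),
        "offset": float(-off if flipped else off),
        "residual": float(np.sum(sol.fun**2)),
        "n_evaluations": int(sol.nfev),
        "converged": bool(sol.success),
        "sign_flipped": flipped,
    }
    return GaussianRF(mu=np.array([mx, my]), sigma=sigma,
                      pixel_pitch=spatial_rf.pixel_pitch, fit_info=info)


def effective_diameter(rf: GaussianRF) -> float:
    """Effective RF diameter d = sqrt(a*b) in micrometers.

    a and b are the full major/minor axis lengths of the 1.5-sigma
    contour ellipse, i.e. 2 * 1.5 * sqrt(eigenvalue) = 3 sqrt(lambda)
    pixels along each principal direction.
    """
    lam = np.linalg.eigvalsh(rf.sigma)
    a = 3.0 * np.sqrt(lam[1])
    b = 3.0 * np.sqrt(lam[0])
    return float(np.sqrt(a * b) * rf.pixel_pitch)


def contour_mask(rf: GaussianRF, n_sigma: float, shape: tuple[int, int]) -> tuple[np.ndarray, int]:
    """Boolean mask of pixel centers within the n-sigma Mahalanobis ellipse.

    Returns (mask, N) where N is the number of pixels inside the contour.
    """
    if n_sigma <= 0:
        raise ValueError("n_sigma must be positive")
    mask = rf.mahalanobis_sq(shape) <= n_sigma**2
    return mask, int(mask.sum())
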