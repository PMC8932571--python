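"""Synthetic stimuli and ground-truth model cells.

Everything downstream of a retinal recording — receptive-field
estimation, image statistics, encoding-model fits, paired-difference and
spatial-scale analyses — is exercised here on generated data with known
ground truth:

* natural-like images: Gaussian random fields with a power-law amplitude
  spectrum, standardized to zero-mean Weber contrast with SD 0.5;
* binary checkerboard white-noise movies for reverse correlation;
* model cells that are either spatially linear (drive = signed I_mean
  under the true RF) or subunit cells that pool half-wave-rectified
  local contrast signals — the minimal mechanism producing sensitivity
  to local spatial contrast;
* spike counts with calibrated sub-Poissonian trial-to-trial
  variability (binomial thinning), or Poisson / deterministic controls.

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .cell_metrics import ResponseTable
from .image_features import ContrastImage, standardize_contrast
from .receptive_field import GaussianRF, contour_mask

__all__ = [
    "SyntheticImageSetSpec",
    "StimulusMovie",
    "NoiseSpec",
    "SyntheticCell",
    "generate_images",
    "generate_checkerboard_noise",
    "simulate_flash_responses",
    "simulate_white_noise_spikes",
    "expected_counts",
    "cell_drive",
    "draw_counts",
    "biphasic_temporal_filter",
    "make_linear_cell",
    "make_subunit_cell",
]


# --------------------------------------------------------------------------
# image generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticImageSetSpec:
    """Parameters of a natural-like image ensemble.

    ``spectral_exponent`` sets the power-law decay of the spatial
    amplitude spectrum (0 = white noise, 1 = roughly natural 1/f);
    ``target_sd_fraction`` is the contrast SD as a fraction of the mean
    intensity (0.5 emulates display preparation of flashed photographs).
    """

    n_images: int = 300
    size_px: int = 128
    pixel_pitch: float = 7.5  # micrometers per pixel
    spectral_exponent: float = 1.0
    target_sd_fraction: float = 0.5
    contrast_modulation: float = 0.8
    modulation_scale_um: float = 240.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 2:
            raise ValueError("n_images must be at least 2")
        if self.size_px < 8:
            raise ValueError("size_px must be at least 8")
        if not 0 < self.target_sd_fraction <= 1:
            raise ValueError("target_sd_fraction must lie in (0, 1]")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.contrast_modulation < 0:
            raise ValueError("contrast_modulation must be nonnegative")


def generate_images(spec: SyntheticImageSetSpec) -> list[ContrastImage]:
    """Generate standardized natural-like contrast images.

    Each image is a Gaussian random field whose Fourier amplitudes are
    scaled by f^(-spectral_exponent), multiplied by a smooth lognormal
    contrast envelope (exp of a low-pass Gaussian field with log-SD
    ``contrast_modulation`` and correlation scale ``modulation_scale_um``),
    then standardized to zero-mean contrast with SD ``target_sd_fraction``
    and clipped to [-1, +1].

    The envelope emulates the patchy local-contrast structure of natural
    scenes (approximately lognormal local contrast): without it, a
    stationary Gaussian field has nearly identical local spatial contrast
    in every image, which no retinal image ensemble does.  Setting
    ``contrast_modulation=0`` recovers the plain stationary field.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size_px
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    f = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        amp = np.where(f > 0, f ** (-spec.spectral_exponent), 0.0)
    mod_px = spec.modulation_scale_um / spec.pixel_pitch
    images = []
    for _ in range(spec.n_images):
        white = rng.standard_normal((n, n))
        fieldimg = np.fft.ifft2(np.fft.fft2(white) * amp).real
        if spec.contrast_modulation > 0:
            mod = gaussian_filter(rng.standard_normal((n, n)), mod_px, mode="wrap")
            sd = mod.std()
            if sd > 0:
                mod = (mod - mod.mean()) / sd
            fieldimg = fieldimg * np.exp(spec.contrast_modulation * mod)
        img, _ = standardize_contrast(
            fieldimg, target_sd=spec.target_sd_fraction, pixel_pitch=spec.pixel_pitch
        )
        images.append(img)
    return images


# --------------------------------------------------------------------------
# checkerboard white noise
# --------------------------------------------------------------------------

@dataclass
class StimulusMovie:
    """Binary checkerboard white-noise movie (frames x y x x, values +/-1)."""

    frames: np.ndarray
    frame_rate: float = 30.0
    pixel_pitch: float = 7.5  # micrometers per pixel
    square_px: int = 4

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, y, x) stack")
        if not np.all(np.isin(self.frames, (-1, 1))):
            raise ValueError("checkerboard frames must be binary +/-1 contrast")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def square_size_um(self) -> float:
        return self.square_px * self.pixel_pitch


def generate_checkerboard_noise(
    n_frames: int,
    grid_px: int,
    square_px: int,
    seed: int = 0,
    frame_rate: float = 30.0,
    pixel_pitch: float = 7.5,
) -> StimulusMovie:
    """Spatiotemporal binary white noise on a checkerboard layout.

    Each square of ``square_px`` x ``square_px`` pixels independently
    takes contrast -1 or +1 with probability 1/2 on every frame
    (100% Michelson contrast).
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if grid_px % square_px != 0:
        raise ValueError(f"grid ({grid_px} px) not divisible into {square_px}-px squares")
    rng = np.random.default_rng(seed)
    n_sq = grid_px // square_px
    squares = (rng.integers(0, 2, size=(n_frames, n_sq, n_sq), dtype=np.int8) * 2 - 1)
    frames = squares.repeat(square_px, axis=1).repeat(square_px, axis=2)
    return StimulusMovie(frames=frames, frame_rate=frame_rate,
                         pixel_pitch=pixel_pitch, square_px=square_px)


# --------------------------------------------------------------------------
# trial-to-trial noise
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Trial-to-trial spike-count noise model.

    ``sub-poisson-thinned`` draws counts from a mean-matched mixture of
    the adjacent-integer law floor(rate)+Bernoulli(frac) — the integer
    distribution of minimal variance — and a thinned binomial
    Binomial(n, rate/n).  The mixture weight is chosen so the Fano
    factor equals target_fano exactly whenever that is attainable for an
    integer-valued law of the given mean; at very low rates, where even
    the minimal-variance law exceeds the target, the minimal-variance
    law is used alone.
    """

    family: str = "sub-poisson-thinned"
    target_fano: float = 0.3

    def __post_init__(self) -> None:
        if self.family not in ("sub-poisson-thinned", "poisson", "deterministic"):
            raise ValueError(f"unknown noise family: {self.family!r}")
        if self.family == "sub-poisson-thinned" and not 0 < self.target_fano <= 1:
            raise ValueError("target_fano must lie in (0, 1] for thinned noise")


def draw_counts(rates: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw integer spike counts with the requested noise family."""
    rates = np.maximum(np.asarray(rates, dtype=float), 0.0)
    if noise.family == "deterministic":
        return np.round(rates).astype(int)
    if noise.family == "poisson":
        return rng.poisson(rates)
    f = noise.target_fano
    q = 1.0 - f
    shape = rates.shape
    r = rates.ravel()
    base = np.floor(r)
    frac = r - base
    with np.errstate(divide="ignore", invalid="ignore"):
        ff_lo = np.where(r > 0, frac * (1 - frac) / r, 0.0)
    # high-variance component: thinned binomial with Fano 1 - r/n > f
    n_hi = np.maximum(np.floor(r / q) + 1, np.ceil(r)).astype(int)
    n_hi = np.maximum(n_hi, 1)
    q_hi = np.where(r > 0, r / n_hi, 0.0)
    ff_hi = 1.0 - q_hi
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(ff_hi > ff_lo, (ff_hi - f) / (ff_hi - ff_lo), 1.0)
    lam = np.clip(lam, 0.0, 1.0)  # lam=1 where even minimal variance > target
    use_lo = rng.random(r.shape) < lam
    lo = base.astype(int) + (rng.random(r.shape) < frac)
    hi = rng.binomial(n_hi, q_hi)
    return np.where(use_lo, lo, hi).reshape(shape)


# --------------------------------------------------------------------------
# model cells
# --------------------------------------------------------------------------

def biphasic_temporal_filter(
    n_lags: int = 15,
    peak_lag: float = 2.0,
    rebound_lag: float = 6.0,
    rebound_ratio: float = 0.5,
    polarity: str = "ON",
) -> np.ndarray:
    """Unit-norm biphasic temporal filter over STA lags (lag 0 = spike frame).

    Difference of two gamma-shaped bumps; ``peak_lag`` controls the
    kinetics (smaller = faster cell).  The filter's main peak is positive
    for ON cells and negative for OFF cells, matching the STA sign
    convention where the spatial map's peak is positive.
    """
    lags = np.arange(n_lags, dtype=float)

    def bump(center):
        return (lags / center) ** center * np.exp(center - lags)

    f = bump(peak_lag) - rebound_ratio * bump(rebound_lag)
    f /= np.linalg.norm(f)
    if polarity == "OFF":
        f = -f
    return f


# Softplus output-stage defaults, calibrated once so that trial-averaged
# counts of a default cell span roughly 0-12 spikes per flash window --
# the typical dynamic range of flashed-image responses.
LINEAR_OUTPUT_PARAMS = (2.5, 80.0, 0.005)
SUBUNIT_OUTPUT_PARAMS = (2.5, 27.0, -0.08)


@dataclass
class SyntheticCell:
    """Ground-truth generative cell (linear or rectified-subunit pooling).

    For ``kind='linear'`` the pre-nonlinearity drive to an image is the
    polarity-signed RF-weighted mean contrast (the true I_mean).  For
    ``kind='subunit'`` the drive pools half-wave-rectified local contrast
    averages: the signed contrast is low-pass filtered with a circular
    Gaussian of SD ``subunit_sigma_um``, sampled on a square grid of
    subunit centers inside the RF's 3-sigma contour, rectified, and
    summed with weights given by the RF envelope at the centers
    (normalized to sum to 1).  Either drive is passed through the
    softplus output stage r(F) = a1 ln(1 + exp(a2 (F + a3))).
    """

    polarity: str
    rf: GaussianRF
    kind: str = "linear"
    subunit_spacing_um: float | None = None
    subunit_sigma_um: float | None = None
    subunit_nonlinearity: str = "half-wave"
    output_params: tuple[float, float, float] = LINEAR_OUTPUT_PARAMS
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    temporal_filter: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.polarity not in ("ON", "OFF"):
            raise ValueError("polarity must be 'ON' or 'OFF'")
        if self.kind not in ("linear", "subunit"):
            raise ValueError("kind must be 'linear' or 'subunit'")
        if self.kind == "subunit":
            if self.subunit_sigma_um is None or self.subunit_sigma_um <= 0:
                raise ValueError("subunit cells need subunit_sigma_um > 0")
            if self.subunit_spacing_um is None:
                self.subunit_spacing_um = self.subunit_sigma_um
            if self.subunit_spacing_um <= 0:
                raise ValueError("subunit_spacing_um must be positive")
            if self.subunit_nonlinearity not in ("half-wave", "identity"):
                raise ValueError("subunit nonlinearity must be 'half-wave' or 'identity'")
        else:
            if self.subunit_sigma_um is not None or self.subunit_spacing_um is not None:
                raise ValueError("subunit fields are only valid for kind='subunit'")
        a1, a2, _ = self.output_params
        if a1 < 0 or a2 <= 0:
            raise ValueError("output params must give nonnegative rates (a1 >= 0, a2 > 0)")
        if self.temporal_filter is None:
            self.temporal_filter = biphasic_temporal_filter(polarity=self.polarity)
        else:
            self.temporal_filter = np.asarray(self.temporal_filter, dtype=float)

    @property
    def sign(self) -> float:
        return 1.0 if self.polarity == "ON" else -1.0

    def subunit_centers(self, shape: tuple[int, int]) -> np.ndarray:
        """Square-grid subunit centers (x, y in px) inside the 3-sigma contour."""
        spacing_px = self.subunit_spacing_um / self.rf.pixel_pitch
        lam_max = np.linalg.eigvalsh(self.rf.sigma)[-1]
        reach = 3.0 * np.sqrt(lam_max)
        offsets = np.arange(-np.ceil(reach / spacing_px), np.ceil(reach / spacing_px) + 1)
        gx, gy = np.meshgrid(offsets * spacing_px + self.rf.mu[0],
                             offsets * spacing_px + self.rf.mu[1])
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        d = pts - self.rf.mu
        prec = np.linalg.inv(self.rf.sigma)
        maha2 = np.einsum("ni,ij,nj->n", d, prec, d)
        return pts[maha2 <= 9.0]


def _softplus(f, a1, a2, a3):
    return a1 * np.logaddexp(0.0, a2 * (np.asarray(f, dtype=float) + a3))


def cell_drive(cell: SyntheticCell, image: ContrastImage) -> float:
    """Pre-softplus drive of a ground-truth cell for one contrast image."""
    shape = image.shape
    if cell.kind == "linear":
        mask, n = contour_mask(cell.rf, 3.0, shape)
        if n == 0:
            raise ValueError("RF contour does not overlap the image")
        g = cell.rf.weights(shape)
        return float(cell.sign * (g[mask] * image.values[mask]).mean())
    # subunit pooling
    sigma_px = cell.subunit_sigma_um / image.pixel_pitch
    local = gaussian_filter(cell.sign * image.values, sigma=sigma_px, mode="reflect")
    centers = cell.subunit_centers(shape)
    if centers.shape[0] == 0:
        raise ValueError("no subunit centers fall inside the RF contour")
    ix = np.clip(np.round(centers[:, 0]).astype(int), 0, shape[1] - 1)
    iy = np.clip(np.round(centers[:, 1]).astype(int), 0, shape[0] - 1)
    u = local[iy, ix]
    if cell.subunit_nonlinearity == "half-wave":
        u = np.maximum(u, 0.0)
    d = centers - cell.rf.mu
    prec = np.linalg.inv(cell.rf.sigma)
    env = np.exp(-0.5 * np.einsum("ni,ij,nj->n", d, prec, d))
    env = env / env.sum()
    return float(np.sum(env * u))


def expected_counts(cell: SyntheticCell, images) -> np.ndarray:
    """Noise-free expected spike count per image (softplus of the drive)."""
    a1, a2, a3 = cell.output_params
    drives = np.array([cell_drive(cell, img) for img in images])
    return _softplus(drives, a1, a2, a3)


def simulate_flash_responses(
    cell: SyntheticCell,
    images,
    n_trials: int,
    seed: int = 0,
    window_ms: tuple[float, float] = (0.0, 300.0),
) -> ResponseTable:
    """Per-trial spike counts of a ground-truth cell to flashed images."""
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    rates = expected_counts(cell, images)
    rng = np.random.default_rng(seed)
    counts = draw_counts(np.tile(rates[:, None], (1, n_trials)), cell.noise, rng)
    return ResponseTable(counts=counts, window_ms=window_ms)


def simulate_white_noise_spikes(
    cell: SyntheticCell,
    movie: StimulusMovie,
    seed: int = 0,
    drive_sd: float = 0.04,
) -> np.ndarray:
    """Inhomogeneous-Poisson spikes of a cell driven by checkerboard noise.

    The movie is filtered spatially by the unit-norm RF kernel and
    temporally by the cell's temporal filter; the resulting drive is
    standardized to SD ``drive_sd`` (the typical spread of I_mean over
    flashed natural-like scenes, so the cell's flash-calibrated softplus
    operates in its normal range) and passed through the softplus output
    stage.  The softplus output is read as spikes per 300-ms flash window
    and converted to a per-frame Poisson rate.
    """
    tf = cell.temporal_filter
    if movie.n_frames <= tf.size:
        raise ValueError("movie shorter than the cell's temporal filter support")
    shape = movie.frames.shape[1:]
    g = cell.rf.weights(shape)
    gn = g / np.linalg.norm(g)
    x = np.tensordot(movie.frames.astype(np.float32), gn.astype(np.float32), axes=([1, 2], [0, 1]))
    x = x.astype(float)
    drive = np.convolve(x, tf)[: movie.n_frames]
    # analytic drive SD: squares are iid +/-1, so var = sum over squares of
    # (kernel mass in the square)^2; temporal filter has unit norm.
    sp = movie.square_px
    ny, nx = shape
    mass = gn[: ny - ny % sp, : nx - nx % sp].reshape(ny // sp, sp, nx // sp, sp).sum(axis=(1, 3))
    sd_x = float(np.sqrt(np.sum(mass**2)))
    if sd_x > 0:
        drive = drive * (drive_sd / sd_x)
    a1, a2, a3 = cell.output_params
    rate_window = _softplus(drive, a1, a2, a3)  # spikes per 300-ms window
    lam = rate_window / 0.3 / movie.frame_rate  # spikes per frame
    rng = np.random.default_rng(seed)
    n_per_frame = rng.poisson(lam)
    total = int(n_per_frame.sum())
    if total == 0:
        return np.empty(0)
    frame_of_spike = np.repeat(np.arange(movie.n_frames), n_per_frame)
    times = (frame_of_spike + rng.random(total)) / movie.frame_rate
    return np.sort(times)


# --------------------------------------------------------------------------
# cell factories
# --------------------------------------------------------------------------

def _circular_rf(center_px, sigma_um: float, pixel_pitch: float) -> GaussianRF:
    s_px = sigma_um / pixel_pitch
    return GaussianRF(mu=np.asarray(center_px, dtype=float),
                      sigma=np.eye(2) * s_px**2, pixel_pitch=pixel_pitch)


def make_linear_cell(
    center_px=(63.5, 63.5),
    sigma_um: float = 100.0,
    pixel_pitch: float = 7.5,
    polarity: str = "OFF",
    noise: NoiseSpec | None = None,
    output_params: tuple[float, float, float] | None = None,
    temporal_peak_lag: float = 2.0,
) -> SyntheticCell:
    """Spatially linear model cell with a circular Gaussian RF."""
    return SyntheticCell(
        polarity=polarity,
        rf=_circular_rf(center_px, sigma_um, pixel_pitch),
        kind="linear",
        output_params=output_params or LINEAR_OUTPUT_PARAMS,
        noise=noise or NoiseSpec(),
        temporal_filter=biphasic_temporal_filter(peak_lag=temporal_peak_lag, polarity=polarity),
    )


def make_subunit_cell(
    center_px=(63.5, 63.5),
    sigma_um: float = 130.0,
    pixel_pitch: float = 7.5,
    polarity: str = "OFF",
    subunit_diameter_um: float = 60.0,
    subunit_spacing_um: float | None = None,
    noise: NoiseSpec | None = None,
    output_params: tuple[float, float, float] | None = None,
    temporal_peak_lag: float = 2.0,
) -> SyntheticCell:
    """Rectified-subunit model cell.

    ``subunit_diameter_um`` is the subunit's 3-sigma extent (same
    convention as RF effective diameters), emulating bipolar-cell-scale
    subunits; the Gaussian SD is a third of it.
    """
    sub_sigma = subunit_diameter_um / 3.0
    return SyntheticCell(
        polarity=polarity,
        rf=_circular_rf(center_px, sigma_um, pixel_pitch),
        kind="subunit",
        subunit_sigma_um=sub_sigma,
        subunit_spacing_um=subunit_spacing_um if subunit_spacing_um is not None else sub_sigma,
        output_params=output_params or SUBUNIT_OUTPUT_PARAMS,
        noise=noise or NoiseSpec(),
        temporal_filter=biphasic_temporal_filter(peak_lag=temporal_peak_lag, polarity=polarity),
    )


def with_noise(cell: SyntheticCell, noise: NoiseSpec) -> SyntheticCell:
    """Copy of a cell with a different trial-noise model."""
    return replace(cell, noise=noise)
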