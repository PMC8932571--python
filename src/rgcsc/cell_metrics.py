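"""Spike counting, reliability metrics, polarity and inclusion filters,
and functional clustering of a cell population.

Responses to flashed images are reduced to spike counts in a fixed
post-onset window (300 ms for the salamander preset, 250 ms for the mouse
preset).  Trial-to-trial reliability is quantified by per-image Fano
factors (variance/mean of trial counts); flashed-image responses of
retinal ganglion cells are typically sub-Poissonian (Fano well below 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ResponseTable",
    "count_spikes",
    "fano_factors",
    "classify_polarity_salamander",
    "classify_polarity_mouse",
    "inclusion_filter",
    "odd_even_reliability",
    "cluster_cells",
    "COUNT_WINDOWS_MS",
]

#: Species presets for the spike-count window (ms after image onset).
COUNT_WINDOWS_MS = {"salamander": (0.0, 300.0), "mouse": (0.0, 250.0)}


@dataclass
class ResponseTable:
    """Per-image x per-trial spike counts for one cell."""

    counts: np.ndarray
    window_ms: tuple[float, float] = (0.0, 300.0)
    image_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be an image x trial matrix")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("spike counts must be integers")
            self.counts = self.counts.astype(int)
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("count window start must precede end")
        if self.image_ids is None:
            self.image_ids = np.arange(self.counts.shape[0])
        else:
            self.image_ids = np.asarray(self.image_ids)

    @property
    def n_images(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    @property
    def mean_counts(self) -> np.ndarray:
        """Trial-averaged count per image."""
        return self.counts.mean(axis=1)

    @property
    def var_counts(self) -> np.ndarray:
        """Sample variance (N-1) of trial counts per image."""
        return self.counts.var(axis=1, ddof=1)


def count_spikes(trial_spike_times_ms, window_ms: tuple[float, float] = (0.0, 300.0)) -> ResponseTable:
    """Count spikes in a half-open onset-relative window [start, end).

    ``trial_spike_times_ms`` is a nested sequence: per image, per trial,
    an array of spike times in ms relative to image onset.  A spike at
    exactly the window end is excluded (half-open convention).
    """
    start, end = window_ms
    counts = np.array(
        [
            [int(np.sum((np.asarray(t, dtype=float) >= start) & (np.asarray(t, dtype=float) < end)))
             for t in image_trials]
            for image_trials in trial_spike_times_ms
        ],
        dtype=int,
    )
    return ResponseTable(counts=counts, window_ms=window_ms)


def fano_factors(table: ResponseTable) -> tuple[np.ndarray, float]:
    """Per-image Fano factors (var/mean of trial counts) and the cell average.

    Images with zero total spikes are excluded (their Fano factor is
    undefined); the per-image array carries NaN there.  The cell-level
    Fano factor is the mean over included images.
    """
    if table.n_trials < 2:
        raise ValueError("Fano factors require at least two trials")
    mean = table.mean_counts
    var = table.var_counts
    ff = np.full(table.n_images, np.nan)
    included = mean > 0
    ff[included] = var[included] / mean[included]
    if not included.any():
        raise ValueError("all images have zero spikes; Fano factor undefined")
    return ff, float(np.nanmean(ff))


def _ratio_class(num: float, den: float, threshold: float) -> bool:
    """num/den > threshold, with zero denominators read as infinite ratio."""
    if den == 0:
        return num > 0
    return num / den > threshold


def classify_polarity_salamander(n_black: float, n_white: float) -> str:
    """Polarity from full-field +/-100% contrast steps: OFF if B/W > 3, ON if W/B > 3."""
    if n_black < 0 or n_white < 0:
        raise ValueError("spike numbers must be nonnegative")
    if _ratio_class(n_black, n_white, 3.0):
        return "OFF"
    if _ratio_class(n_white, n_black, 3.0):
        return "ON"
    return "ON-OFF"


def classify_polarity_mouse(table: ResponseTable, i_mean: np.ndarray) -> str:
    """Polarity from flashed-image responses split by the sign of I_mean.

    R_on is the mean count over images with I_mean > 0, R_off over images
    with I_mean < 0 (I_mean = 0 images are excluded).  ON if
    R_on > 2 R_off, OFF if R_off > 2 R_on, else ON-OFF.
    """
    i_mean = np.asarray(i_mean, dtype=float)
    if i_mean.shape[0] != table.n_images:
        raise ValueError("i_mean length must match the number of images")
    mean = table.mean_counts
    on_imgs = i_mean > 0
    off_imgs = i_mean < 0
    if not on_imgs.any() or not off_imgs.any():
        raise ValueError("need images of both signs of I_mean")
    r_on = float(mean[on_imgs].mean())
    r_off = float(mean[off_imgs].mean())
    if _ratio_class(r_on, r_off, 2.0):
        return "ON"
    if _ratio_class(r_off, r_on, 2.0):
        return "OFF"
    return "ON-OFF"


def odd_even_reliability(table: ResponseTable) -> float:
    """Symmetrized coefficient of determination between odd and even trials.

    Trials are split by parity; per-image mean vectors o and e are
    compared with

        R2_sym = 1 - sum_i (o_i - e_i)^2
                     / sum_i [ (o_i - m)^2 + (e_i - m)^2 ],

    m being the grand mean of both halves.  Identical halves give 1;
    independent noise gives approximately 0.
    """
    if table.n_trials < 2:
        raise ValueError("reliability requires at least two trials")
    even = table.counts[:, 0::2].mean(axis=1)
    odd = table.counts[:, 1::2].mean(axis=1)
    m = 0.5 * (even.mean() + odd.mean())
    denom = np.sum((odd - m) ** 2 + (even - m) ** 2)
    if denom == 0:
        return 1.0  # both halves constant and equal
    return float(1.0 - np.sum((odd - even) ** 2) / denom)


def inclusion_filter(
    table: ResponseTable,
    species: str = "salamander",
    polarity: str | None = None,
) -> tuple[bool, list[str]]:
    """Response-quality inclusion filter with species presets.

    Salamander: the maximum trial-averaged count over images must be at
    least 5 spikes.  Mouse: at least 6 spikes, and the odd/even
    reliability must be at least 0.5.  If ``polarity`` is supplied,
    ON-OFF cells are excluded (models assume monotonic contrast-response).
    Returns (included, reasons-for-exclusion).
    """
    reasons: list[str] = []
    max_mean = float(table.mean_counts.max())
    if species == "salamander":
        if max_mean < 5.0:
            reasons.append("max mean count below 5 spikes")
    elif species == "mouse":
        if max_mean < 6.0:
            reasons.append("max mean count below 6 spikes")
        if odd_even_reliability(table) < 0.5:
            reasons.append("reliability")
    else:
        raise ValueError(f"unknown species preset: {species!r}")
    if polarity == "ON-OFF":
        reasons.append("ON-OFF polarity")
    return (len(reasons) == 0), reasons


def cluster_cells(
    diameters_um,
    temporal_filters,
    k: int = 4,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Functional clustering on RF size and temporal-filter kinetics.

    The temporal filters (equal length, unit norm) are centered and
    projected onto their first principal component; k-means (multiple
    initializations, best inertia) is run on the two z-scored features
    (effective diameter, PC1 projection).  Returns (labels, pc1).
    """
    d = np.asarray(diameters_um, dtype=float)
    tf = np.asarray([np.asarray(t.weights if hasattr(t, "weights") else t, dtype=float)
                     for t in temporal_filters])
    if tf.ndim != 2 or tf.shape[0] != d.shape[0]:
        raise ValueError("need one equal-length temporal filter per cell")
    n = d.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} cells, got {n}")
    pc1 = PCA(n_components=1).fit_transform(tf - tf.mean(axis=0)).ravel()

    def z(x):
        s = x.std()
        return (x - x.mean()) / s if s > 0 else x - x.mean()

    feats = np.column_stack([z(d), z(pc1)])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(feats)
    return labels, pc1
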