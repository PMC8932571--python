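"""Paired-difference analysis: isolating spatial-contrast effects.

Spike count depends strongly on the mean stimulus intensity I_mean, which
masks any additional effect of local spatial contrast.  Ordering all
images by I_mean and differencing adjacent neighbors (hi - lo) removes
the mean-intensity dependence almost completely — neighboring images have
nearly equal I_mean — so correlations between the spike-count differences
(dSpikes) and the contrast differences (dLSC) expose a genuine
sensitivity to spatial structure.  A spatially linear cell shows no such
correlation; a subunit cell shows a clearly positive one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr

__all__ = ["make_pairs", "pair_correlations"]


def make_pairs(features: pd.DataFrame, mean_counts) -> pd.DataFrame:
    """Adjacent-neighbor pairs in the I_mean ordering.

    ``features`` needs columns ``image_id``, ``i_mean``, ``lsc``;
    ``mean_counts`` is the trial-averaged spike count aligned with the
    rows.  Images are stably sorted by (i_mean, image_id) — ties keep
    image-id order — and all n-1 adjacent pairs are differenced
    (next - current).
    """
    df = features.copy()
    counts = np.asarray(mean_counts, dtype=float)
    if len(df) != counts.size:
        raise ValueError("mean_counts must align with the feature rows")
    if len(df) < 2:
        raise ValueError("need at least 2 images to form pairs")
    df = df.assign(mean_count=counts)
    order = np.lexsort((df["image_id"].to_numpy(), df["i_mean"].to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    lo = df.iloc[:-1].reset_index(drop=True)
    hi = df.iloc[1:].reset_index(drop=True)
    return pd.DataFrame(
        {
            "image_lo": lo["image_id"].to_numpy(),
            "image_hi": hi["image_id"].to_numpy(),
            "d_imean": hi["i_mean"].to_numpy() - lo["i_mean"].to_numpy(),
            "d_lsc": hi["lsc"].to_numpy() - lo["lsc"].to_numpy(),
            "d_spikes": hi["mean_count"].to_numpy() - lo["mean_count"].to_numpy(),
        }
    )


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")  # undefined for constant difference vectors
    return float(pearsonr(x, y).statistic)


def pair_correlations(pairs: pd.DataFrame) -> dict:
    """Pearson correlations among the three difference vectors.

    Returns ``r_dimean_dspikes``, ``r_dlsc_dspikes``, ``r_dimean_dlsc``
    and the least-squares slope of dSpikes on dLSC.  Entries involving a
    constant vector are NaN (correlation undefined).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    di = pairs["d_imean"].to_numpy(dtype=float)
    dl = pairs["d_lsc"].to_numpy(dtype=float)
    ds = pairs["d_spikes"].to_numpy(dtype=float)
    out = {
        "r_dimean_dspikes": _corr(di, ds),
        "r_dlsc_dspikes": _corr(dl, ds),
        "r_dimean_dlsc": _corr(di, dl),
    }
    if np.ptp(dl) == 0:
        out["slope_dlsc_dspikes"] = float("nan")
    else:
        out["slope_dlsc_dspikes"] = float(linregress(dl, ds).slope)
    return out
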