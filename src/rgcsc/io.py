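"""File formats for stimuli, responses, receptive fields and models.

Images travel as 16-bit single-channel TIFFs with a JSON sidecar holding
the pixel pitch and the contrast scaling; movies as HDF5 stacks; spike
counts, features and fitted-parameter tables as plain CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .cell_metrics import ResponseTable
from .image_features import ContrastImage
from .receptive_field import GaussianRF
from .synthetic import StimulusMovie

__all__ = [
    "save_images",
    "load_images",
    "save_movie",
    "load_movie",
    "save_counts",
    "load_counts",
    "save_rf",
    "load_rf",
    "save_model",
    "load_model",
]

_CONTRAST_LO, _CONTRAST_HI = -1.0, 1.0


def save_images(images: list[ContrastImage], directory) -> None:
    """Write contrast images as 16-bit TIFFs plus a JSON sidecar.

    Contrast in [-1, +1] maps linearly onto the uint16 range.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"pixel_pitch_um": images[0].pixel_pitch,
            "contrast_range": [_CONTRAST_LO, _CONTRAST_HI],
            "n_images": len(images)}
    with open(directory / "images.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    for i, img in enumerate(images):
        scaled = (img.values - _CONTRAST_LO) / (_CONTRAST_HI - _CONTRAST_LO)
        tifffile.imwrite(directory / f"image_{i:04d}.tif",
                         np.round(scaled * 65535).astype(np.uint16))


def load_images(directory) -> list[ContrastImage]:
    directory = Path(directory)
    with open(directory / "images.json") as fh:
        meta = json.load(fh)
    lo, hi = meta["contrast_range"]
    out = []
    for i in range(meta["n_images"]):
        raw = tifffile.imread(directory / f"image_{i:04d}.tif").astype(float) / 65535.0
        out.append(ContrastImage(values=raw * (hi - lo) + lo,
                                 pixel_pitch=meta["pixel_pitch_um"]))
    return out


def save_movie(movie: StimulusMovie, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("frames", data=movie.frames.astype(np.int8),
                               compression="gzip")
        ds.attrs["frame_rate"] = movie.frame_rate
        ds.attrs["pixel_pitch_um"] = movie.pixel_pitch
        ds.attrs["square_px"] = movie.square_px


def load_movie(path) -> StimulusMovie:
    with h5py.File(path, "r") as fh:
        ds = fh["frames"]
        return StimulusMovie(frames=ds[...],
                             frame_rate=float(ds.attrs["frame_rate"]),
                             pixel_pitch=float(ds.attrs["pixel_pitch_um"]),
                             square_px=int(ds.attrs["square_px"]))


def save_counts(table: ResponseTable, path, cell_id: int = 0) -> None:
    """Long-format CSV: cell_id, image_id, trial, count."""
    n_img, n_tr = table.counts.shape
    df = pd.DataFrame({
        "cell_id": cell_id,
        "image_id": np.repeat(table.image_ids, n_tr),
        "trial": np.tile(np.arange(n_tr), n_img),
        "count": table.counts.ravel(),
    })
    df.to_csv(path, index=False)


def load_counts(path, cell_id: int | None = None,
                window_ms: tuple[float, float] = (0.0, 300.0)) -> ResponseTable:
    df = pd.read_csv(path)
    if cell_id is not None:
        df = df[df["cell_id"] == cell_id]
    pivot = df.pivot_table(index="image_id", columns="trial", values="count")
    return ResponseTable(counts=pivot.to_numpy(), window_ms=window_ms,
                         image_ids=pivot.index.to_numpy())


def save_rf(rf: GaussianRF, path, spatial=None, temporal=None, sta=None) -> None:
    """HDF5 bundle of an RF fit and, optionally, its STA factors."""
    with h5py.File(path, "w") as fh:
        fh.attrs["mu"] = rf.mu
        fh.attrs["sigma"] = rf.sigma
        fh.attrs["pixel_pitch_um"] = rf.pixel_pitch
        if spatial is not None:
            fh.create_dataset("spatial", data=np.asarray(spatial))
        if temporal is not None:
            fh.create_dataset("temporal", data=np.asarray(temporal))
        if sta is not None:
            fh.create_dataset("sta", data=np.asarray(sta))


def load_rf(path) -> GaussianRF:
    with h5py.File(path, "r") as fh:
        return GaussianRF(mu=fh.attrs["mu"][:], sigma=fh.attrs["sigma"][:],
                          pixel_pitch=float(fh.attrs["pixel_pitch_um"]))


def save_model(model, path) -> None:
    """Model parameters and fit metadata as JSON."""
    payload = {"a1": model.a1, "a2": model.a2, "a3": model.a3,
               "model": type(model).__name__}
    if hasattr(model, "w"):
        payload["w"] = model.w
    payload["fit_info"] = {k: v for k, v in model.fit_info.items()
                           if k != "sse_trace"}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path):
    from .encoding import LNModel, SCModel
    with open(path) as fh:
        payload = json.load(fh)
    info = payload.get("fit_info", {})
    if payload.get("model") == "SCModel":
        return SCModel(a1=payload["a1"], a2=payload["a2"], a3=payload["a3"],
                       w=payload["w"], fit_info=info)
    return LNModel(a1=payload["a1"], a2=payload["a2"], a3=payload["a3"],
                   fit_info=info)
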