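"""Movie readers/writers: MRC (modes 0/1/2/6) and TIFF, with JSON sidecars.

MRC headers cannot carry the acquisition metadata this analysis needs
(frame period, super-resolution factor, per-event value, gain flag), so a
sidecar JSON file ``<movie>.json`` travels with each movie.  Reading a
movie without a sidecar falls back to explicit defaults with warnings.
"""

from __future__ import annotations

import json
import os
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .movie import MovieMetadata, SuperResMovie
from .mrc import read_mrc, write_mrc

__all__ = ["read_movie", "write_movie", "sidecar_path"]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_movie(movie: SuperResMovie, path, mode: str | int = "auto",
                sidecar: bool = True) -> None:
    """Write a movie as MRC (or TIFF by extension) plus a metadata sidecar.

    ``mode`` selects the MRC data type: ``"auto"`` picks unsigned 8-bit
    when all counts fit (the camera's native movie format) and unsigned
    16-bit otherwise; explicit 0/1/2/6 are honoured when the data fit.
    """
    path = Path(path)
    data = movie.data
    vmax = int(data.max(initial=0))
    vmin = int(data.min(initial=0))
    if path.suffix.lower() in _TIFF_SUFFIXES:
        dtype = np.uint8 if vmax <= 255 and vmin >= 0 else np.uint16
        tifffile.imwrite(path, data.astype(dtype))
    else:
        if mode == "auto":
            mode = 0 if 0 <= vmin and vmax <= 255 else 6
        limits = {0: (0, 255), 1: (-32768, 32767), 2: None, 6: (0, 65535)}
        if mode not in limits:
            raise ValueError(f"unsupported MRC mode {mode!r}")
        if limits[mode] is not None:
            lo, hi = limits[mode]
            if vmin < lo or vmax > hi:
                raise ValueError(
                    f"counts [{vmin}, {vmax}] do not fit MRC mode {mode}")
        dtype = {0: np.uint8, 1: np.int16, 2: np.float32, 6: np.uint16}[mode]
        sr_pixel = (movie.pixel_size / movie.superres_factor
                    if movie.pixel_size else None)
        write_mrc(path, data.astype(dtype), voxel_size=sr_pixel)
    if sidecar:
        meta = movie.metadata().to_dict()
        meta["exposure_time"] = movie.exposure_time
        with open(sidecar_path(path), "w") as fh:
            json.dump(meta, fh, indent=1)


def read_movie(path) -> tuple[SuperResMovie, MovieMetadata]:
    """Load an MRC or TIFF movie and its metadata.

    Counts are loaded integer-preserving.  Metadata come from the sidecar
    JSON when present; otherwise defaults (60 frames/s, super-resolution
    factor 2, event value 16) are used and a warning names each field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        data = np.asarray(tifffile.imread(path))
        if data.ndim == 2:
            data = data[None]
        voxel = None
    else:
        data, header = read_mrc(path)
        voxel = header["voxel_size"]
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: float movie with non-integer counts")
        data = np.round(data).astype(np.int64)

    sc = sidecar_path(path)
    exposure: Optional[float] = None
    if sc.exists():
        with open(sc) as fh:
            d = json.load(fh)
        exposure = d.pop("exposure_time", None)
        meta = MovieMetadata.from_dict(d)
        meta.n_frames = data.shape[0]
    else:
        meta = MovieMetadata(n_frames=data.shape[0])
        for field in ("frame_period", "superres_factor", "electron_value"):
            warnings.warn(
                f"{os.path.basename(path)}: no metadata sidecar; assuming "
                f"{field} = {getattr(meta, field)}", stacklevel=2)
    if meta.pixel_size is None and voxel:
        meta.pixel_size = voxel * meta.superres_factor

    movie = SuperResMovie(
        data=data, frame_period=meta.frame_period, exposure_time=exposure,
        pixel_size=meta.pixel_size, superres_factor=meta.superres_factor,
        electron_value=meta.electron_value,
    )
    return movie, meta
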