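"""Containers for counted super-resolution movies and their metadata.

A counting detector localizes each detected electron to one sub-pixel of a
physical pixel and records a fixed integer value per event (16 on the
detector emulated here).  Frames are dose fractions with a fixed period.
All dose-rate arithmetic in this package is per *physical* pixel; the
conversion from super-resolution intensities happens in
:func:`countdet.dose.intensity_to_detected_eps`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = ["SuperResMovie", "MovieMetadata"]


@dataclass
class MovieMetadata:
    """Acquisition metadata that MRC headers cannot fully carry.

    Attributes
    ----------
    pixel_size:
        Physical pixel size at the specimen plane, in Angstrom per
        physical pixel.  ``None`` when unknown (flood/beam-off data do not
        need it).
    frame_period:
        Seconds per movie frame.
    n_frames:
        Number of frames in the movie.
    superres_factor:
        Sub-pixel subdivision per physical-pixel axis (1 = physical
        sampling, 2 = super resolution).
    gain_corrected:
        Whether gain correction was applied.  Characterization data are
        acquired with gain correction off so that raw counts are analysed.
    electron_value:
        Recorded intensity per detected electron.
    """

    pixel_size: Optional[float] = None
    frame_period: float = 1.0 / 60.0
    n_frames: int = 1
    superres_factor: int = 2
    gain_corrected: bool = False
    electron_value: int = 16

    def __post_init__(self) -> None:
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if self.superres_factor not in (1, 2):
            raise ValueError("superres_factor must be 1 or 2")
        if self.electron_value < 1:
            raise ValueError("electron_value must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MovieMetadata":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class SuperResMovie:
    """A stack of counted super-resolution frames.

    ``data`` has shape ``(n_frames, ny, nx)`` where ``ny, nx`` are
    super-resolution dimensions (``superres_factor`` x the physical grid).
    Values are integer counts: ``electron_value`` per detected event.

    ``exposure_time`` is the true accumulated exposure in seconds.  It can
    differ from ``n_frames * frame_period`` when a simulation accumulated
    many internal frames into a single output frame.
    """

    data: np.ndarray
    frame_period: float = 1.0 / 60.0
    exposure_time: Optional[float] = None
    pixel_size: Optional[float] = None
    superres_factor: int = 2
    electron_value: int = 16
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("movie data must be 2-D or 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("movie data must be integer counts")
        if self.exposure_time is None:
            self.exposure_time = self.n_frames * self.frame_period
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be positive")
        sf = self.superres_factor
        if any(s % sf for s in self.data.shape[1:]):
            raise ValueError("super-res dimensions must be divisible by "
                             "superres_factor")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def superres_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def physical_shape(self) -> tuple[int, int]:
        sf = self.superres_factor
        ny, nx = self.data.shape[1:]
        return ny // sf, nx // sf

    @property
    def n_physical_pixels(self) -> int:
        ny, nx = self.physical_shape
        return ny * nx

    def summed(self, dtype=np.int64) -> np.ndarray:
        """Sum over frames, keeping super-resolution sampling."""
        return self.data.sum(axis=0, dtype=dtype)

    def physical_image(self, dtype=np.int64) -> np.ndarray:
        """Sum over frames and bin sub-pixels back to the physical grid."""
        sf = self.superres_factor
        s = self.summed(dtype=dtype)
        if sf == 1:
            return s
        ny, nx = s.shape
        return s.reshape(ny // sf, sf, nx // sf, sf).sum(axis=(1, 3))

    def metadata(self) -> MovieMetadata:
        return MovieMetadata(
            pixel_size=self.pixel_size,
            frame_period=self.frame_period,
            n_frames=self.n_frames,
            superres_factor=self.superres_factor,
            electron_value=self.electron_value,
        )
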