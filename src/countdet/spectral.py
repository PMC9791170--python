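"""Noise-power-spectrum analysis for counted flood images.

For an ideal counting detector, the rotationally averaged power spectrum
of a flood exposure is white: each detected event is an independent point
deposit, so power is flat at the per-event shot floor.  Coincidence loss
makes the per-pixel counts sub-Poisson (at most one count per counting
window), which suppresses the low-frequency noise power relative to that
floor.  Spectra are normalized by their mean between 1.5x and 2.0x the
physical Nyquist frequency, where only the event white floor contributes.

Frequency convention: 1.0 = physical Nyquist = 0.5 cycles per physical
pixel.  Super-resolution images sample out to 2.0.

The suppression of the normalized noise power at low frequency measures
the *variance* (power) ratio of the counts, which is the square of the
count-rate efficiency relative to the white floor; the coincidence-loss
fraction therefore corresponds to ``1 - sqrt(NNPS)`` at low frequency,
while ``1 - NNPS`` is the raw power suppression.  Both are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import scipy.fft

from .movie import SuperResMovie

__all__ = [
    "RadialSpectrum", "BandUnavailableError", "radial_power_spectrum",
    "normalize_nps", "nps_suppression", "nps_coincidence_loss",
    "false_positive_rate_estimate",
]

NORM_BAND = (1.5, 2.0)
CL_BAND = (0.06, 0.08)


class BandUnavailableError(ValueError):
    """The requested frequency band is not covered by the spectrum."""


@dataclass(frozen=True)
class RadialSpectrum:
    """Rotationally averaged power spectrum.

    ``freq`` holds bin centers in units of physical Nyquist, strictly
    increasing; ``power`` is the mean raw power per annulus (DC excluded);
    ``counts`` the number of Fourier samples per annulus.  ``norm_band``
    records the normalization interval once applied.
    """

    freq: np.ndarray
    power: np.ndarray
    counts: np.ndarray
    n_bins: int
    norm_band: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if (np.diff(self.freq) <= 0).any():
            raise ValueError("freq must be strictly increasing")
        if (self.power < 0).any():
            raise ValueError("power must be >= 0")

    def band_mean(self, lo: float, hi: float) -> float:
        """Sample-weighted mean power over bins whose centers lie in [lo, hi]."""
        sel = (self.freq >= lo) & (self.freq <= hi) & (self.counts > 0)
        if not sel.any():
            raise BandUnavailableError(
                f"band [{lo}, {hi}] (physical Nyquist units) not covered; "
                f"spectrum spans [{self.freq[0]:.3g}, {self.freq[-1]:.3g}]")
        w = self.counts[sel]
        return float(np.average(self.power[sel], weights=w))


def _central_square(image: np.ndarray) -> np.ndarray:
    ny, nx = image.shape
    n = min(ny, nx)
    n -= n % 2
    y0 = (ny - n) // 2
    x0 = (nx - n) // 2
    return image[y0:y0 + n, x0:x0 + n]


def radial_power_spectrum(image: np.ndarray | SuperResMovie,
                          n_bins: int = 512,
                          superres_factor: Optional[int] = None,
                          ) -> RadialSpectrum:
    """Rotationally averaged raw power spectrum of a flood image.

    A square central crop is taken if the image is rectangular.  The raw
    power is ``|F|**2`` with the unnormalized forward DFT, so the total
    power including DC equals ``N_pixels * sum(image**2)`` (Parseval); this
    identity is asserted.  The DC term is excluded from the annuli.

    ``superres_factor`` sets the frequency axis: 2 means the input samples
    extend to 2x physical Nyquist (super-resolution data), 1 means
    physical-pixel sampling.  It is inferred from a movie input.
    """
    if isinstance(image, SuperResMovie):
        if superres_factor is None:
            superres_factor = image.superres_factor
        image = image.summed().astype(np.float64)
    if superres_factor is None:
        superres_factor = 2
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if min(image.shape) < 64:
        raise ValueError("image must be at least 64 x 64")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    image = _central_square(image)
    n = image.shape[0]

    F = scipy.fft.fft2(image)
    P = np.abs(F) ** 2
    # Parseval consistency for the unnormalized forward transform
    total = P.sum()
    expect = image.size * np.sum(image ** 2)
    if expect > 0 and not np.isclose(total, expect, rtol=1e-8):
        raise AssertionError("Parseval check failed for FFT normalization")
    P[0, 0] = 0.0  # exclude DC

    f1 = np.fft.fftfreq(n)  # cycles per sample
    nyq_phys = 0.5 / superres_factor
    r = np.sqrt(f1[:, None] ** 2 + f1[None, :] ** 2) / nyq_phys
    fmax = float(superres_factor)  # axis Nyquist in physical-Nyquist units

    edges = np.linspace(0.0, fmax, n_bins + 1)
    idx = np.digitize(r.ravel(), edges) - 1
    valid = (idx >= 0) & (idx < n_bins)
    valid[0] = False  # DC
    idx = idx[valid]
    pw = P.ravel()[valid]
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=pw, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        power = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialSpectrum(freq=centers, power=power, counts=counts,
                          n_bins=n_bins)


def normalize_nps(spectrum: RadialSpectrum,
                  band: tuple[float, float] = NORM_BAND) -> RadialSpectrum:
    """Normalize a radial spectrum by its mean power over ``band``.

    The default band, 1.5-2.0x physical Nyquist, exists only for
    super-resolution input; callers with physical-pixel data must supply
    their own band.
    """
    lo, hi = band
    mean = spectrum.band_mean(lo, hi)
    if mean <= 0:
        raise BandUnavailableError("normalization band has zero power")
    return replace(spectrum, power=spectrum.power / mean,
                   norm_band=(float(lo), float(hi)))


def nps_suppression(nnps: RadialSpectrum,
                    band: tuple[float, float] = CL_BAND) -> float:
    """Raw low-frequency power suppression: 1 - mean(NNPS over band).

    This is the literal dip of the normalized noise power spectrum in the
    band (default 0.06-0.08 physical Nyquist, the approximate location of
    the minimum); clipped to [0, 1].
    """
    if nnps.norm_band is None:
        raise ValueError("spectrum must be normalized first (normalize_nps)")
    return float(np.clip(1.0 - nnps.band_mean(*band), 0.0, 1.0))


def nps_coincidence_loss(nnps: RadialSpectrum,
                         band: tuple[float, float] = CL_BAND) -> float:
    """Coincidence-loss estimate from the NNPS low-frequency band.

    The NNPS measures noise *power*, which scales with the per-pixel count
    variance; the count-rate efficiency enters quadratically relative to
    the per-event white floor (for window-limited counting,
    ``NNPS_low = exp(-a x) ~ (1 - CL)**2``).  The coincidence loss is
    therefore estimated as ``1 - sqrt(mean NNPS over band)``, clipped to
    [0, 1].
    """
    if nnps.norm_band is None:
        raise ValueError("spectrum must be normalized first (normalize_nps)")
    m = max(nnps.band_mean(*band), 0.0)
    return float(np.clip(1.0 - np.sqrt(m), 0.0, 1.0))


def false_positive_rate_estimate(beam_off_movie: SuperResMovie) -> float:
    """Dark-count rate (events per physical pixel per second).

    Total counts / per-event value / physical pixels / exposure time.
    """
    if beam_off_movie.exposure_time <= 0:
        raise ValueError("zero exposure time")
    total_events = beam_off_movie.data.sum(dtype=np.float64) \
        / beam_off_movie.electron_value
    return float(total_events / beam_off_movie.n_physical_pixels
                 / beam_off_movie.exposure_time)
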