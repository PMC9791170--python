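"""Slanted-edge MTF estimation, noise-binning DQE(0), and DQE synthesis.

The modulation transfer function is estimated from an image of a straight,
slightly slanted edge (a beamstop in practice): the slant lets the edge
profile be sampled at sub-pixel phases across rows.  Pixels are projected
onto the edge-normal coordinate, binned into an oversampled edge-spread
function (ESF), differentiated into a line-spread function (LSF),
apodized, and Fourier transformed.

DQE(0) uses the noise-binning method: the variance of progressively
block-binned flood images, normalized by bin area times the mean, tends to
the zero-frequency noise power per electron; DQE(0) is the ratio of
detected signal-to-noise to the incident (Poisson) signal-to-noise at
zero frequency.

The full curve is composed as ``DQE(s) = DQE(0) * MTF(s)**2 / NNPS(s)``,
with NNPS taken as unity when not supplied.

Super-resolution inputs are binned to the physical-pixel grid before edge
analysis: counting detectors of this type localize events uniformly
within a physical pixel, so the physical grid carries all the spatial
information and analysing the super-res staircase would fold an extra
sampling factor into the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .movie import SuperResMovie
from .simulate import EdgeAngleError
from .spectral import RadialSpectrum

__all__ = [
    "EdgeFit", "TransferCurves", "Dqe0Result", "PlateauError",
    "fit_edge", "edge_to_mtf", "dqe0_noise_binning", "dqe_curve",
    "theoretical_square_pixel_dqe",
]


class PlateauError(RuntimeError):
    """Noise-binning variance did not reach a zero-frequency plateau."""


@dataclass(frozen=True)
class EdgeFit:
    """Least-squares line through per-row sub-pixel edge locations.

    ``angle`` is in degrees from the image y axis; ``offset`` the edge x
    position (pixels, image coordinates) at row 0 of the ROI; ``transposed``
    is set when the edge was near-horizontal and the image was transposed
    for analysis.
    """

    angle: float
    offset: float
    slope: float
    roi: tuple[int, int, int, int]
    rms_line_residual: float
    transposed: bool = False

    def edge_x(self, rows: np.ndarray) -> np.ndarray:
        """Edge position at given (ROI-relative) row indices."""
        return self.offset + self.slope * np.asarray(rows, dtype=float)


@dataclass
class TransferCurves:
    """MTF and (optionally) DQE on a shared frequency axis.

    ``freq`` in physical-Nyquist units; ``mtf`` normalized to 1 at zero
    frequency; ``dqe0`` and ``dqe`` filled in by :func:`dqe_curve`;
    ``nnps_assumed`` records the NNPS convention used.
    """

    freq: np.ndarray
    mtf: np.ndarray
    dqe0: Optional[float] = None
    dqe: Optional[np.ndarray] = None
    nnps_assumed: str = "unity"

    def __post_init__(self) -> None:
        if not math.isclose(float(self.mtf[0]), 1.0, abs_tol=1e-9):
            raise ValueError("mtf must be normalized to 1 at zero frequency")
        if self.dqe0 is not None and not 0 <= self.dqe0 <= 1.5:
            raise ValueError("dqe0 out of range")

    def at(self, freq: float, curve: str = "mtf") -> float:
        vals = getattr(self, curve)
        if vals is None:
            raise ValueError(f"{curve} not set")
        return float(np.interp(freq, self.freq, vals))


def _to_physical_image(image) -> np.ndarray:
    if isinstance(image, SuperResMovie):
        return image.physical_image().astype(np.float64)
    return np.asarray(image, dtype=np.float64)


def fit_edge(image, roi: Optional[tuple[int, int, int, int]] = None,
             angle_bounds: tuple[float, float] = (1.0, 15.0),
             residual_threshold: float = 1.0,
             smooth_sigma: float = 1.0) -> EdgeFit:
    """Locate a slanted straight edge with sub-pixel precision.

    Per row, the edge position is the centroid of the intensity gradient
    in a window around the strongest gradient; a least-squares line
    through the per-row locations gives angle and offset.  The gradient
    centroid is robust on counted (integer, shot-noise) images where a
    parametric edge-model fit can be brittle.

    Raises :class:`countdet.simulate.EdgeAngleError` when the slant is
    outside ``angle_bounds`` (slanted-edge sampling breaks down) and
    ``ValueError`` when no edge is found or the edge is not straight.
    """
    img = _to_physical_image(image)
    if roi is not None:
        y0, y1, x0, x1 = roi
        img = img[y0:y1, x0:x1]
    else:
        roi = (0, img.shape[0], 0, img.shape[1])
    if min(img.shape) < 24:
        raise ValueError("ROI too small for edge analysis")

    from scipy.ndimage import gaussian_filter1d

    # choose orientation: a near-vertical edge puts its gradient energy in
    # the x direction of every row (sums are per-sample comparable)
    gx_total = float(np.abs(np.diff(img, axis=1)).sum())
    gy_total = float(np.abs(np.diff(img, axis=0)).sum())
    transposed = gy_total > gx_total
    work = img.T if transposed else img

    rows = np.arange(work.shape[0])
    smooth = gaussian_filter1d(work.astype(float), smooth_sigma, axis=1,
                               mode="nearest")
    grad = np.abs(np.diff(smooth, axis=1))
    noise_floor = np.median(grad)
    peak_amp = grad.max(axis=1)
    if grad.max() <= 0 or np.median(peak_amp) < 4 * max(noise_floor, 1e-12):
        raise ValueError("no edge found: gradient too weak in ROI")

    half = max(3, int(math.ceil(4 * smooth_sigma)))
    xs = np.arange(grad.shape[1]) + 0.5  # gradient sample positions
    locs = np.full(len(rows), np.nan)
    for r in rows:
        c = int(np.argmax(grad[r]))
        lo, hi = max(0, c - half), min(grad.shape[1], c + half + 1)
        g = grad[r, lo:hi]
        s = g.sum()
        if s > 0:
            locs[r] = float((xs[lo:hi] * g).sum() / s)
    ok = np.isfinite(locs)
    if ok.sum() < 8:
        raise ValueError("no edge found: too few rows with a usable gradient")

    A = np.vstack([np.ones(ok.sum()), rows[ok].astype(float)]).T
    coef, *_ = np.linalg.lstsq(A, locs[ok], rcond=None)
    offset, slope = float(coef[0]), float(coef[1])
    resid = locs[ok] - A @ coef
    rms = float(np.sqrt(np.mean(resid ** 2)))
    angle = math.degrees(math.atan(slope))

    if rms > 5.0:
        # per-row locations scattered at random: nothing line-like present
        raise ValueError(
            f"no edge found: per-row edge locations are inconsistent "
            f"(rms {rms:.1f} px)")
    lo_a, hi_a = angle_bounds
    if not (lo_a <= abs(angle) <= hi_a):
        raise EdgeAngleError(
            f"edge angle {angle:.2f} deg outside [{lo_a}, {hi_a}] deg: "
            "edge too steep/shallow for the slanted-edge method")
    if rms > residual_threshold:
        raise ValueError(
            f"edge not straight: rms line residual {rms:.2f} px exceeds "
            f"{residual_threshold} px")
    return EdgeFit(angle=angle, offset=offset, slope=slope, roi=roi,
                   rms_line_residual=rms, transposed=transposed)


def edge_to_mtf(image, edge: EdgeFit, oversample: int = 8,
                max_freq: float = 2.0,
                projection_halfwidth: float = 32.0) -> TransferCurves:
    """Slanted-edge MTF from an image and a fitted edge.

    Pixels within ``projection_halfwidth`` physical pixels of the edge are
    projected onto the edge-normal coordinate and binned at
    ``1/oversample`` pixel pitch into an ESF; the LSF is the central
    finite difference, apodized with a Hann window centered on its peak;
    the MTF is the DFT magnitude normalized to 1 at zero frequency,
    reported on the physical-Nyquist frequency axis up to ``max_freq``.

    The projection half-width bounds the noise bandwidth: ESF bins far
    from the edge carry no signal but their differentiated noise enters
    the spectrum.  32 px comfortably contains any LSF this analysis meets
    (the window tapers the cut to zero in any case).
    """
    img = _to_physical_image(image)
    y0, y1, x0, x1 = edge.roi
    img = img[y0:y1, x0:x1]
    work = img.T if edge.transposed else img
    ny, nx = work.shape

    yy, xx = np.meshgrid(np.arange(ny, dtype=float),
                         np.arange(nx, dtype=float), indexing="ij")
    xx = xx + 0.5
    cos_t = math.cos(math.atan(edge.slope))
    d = (xx - (edge.offset + edge.slope * yy)) * cos_t

    keep = np.abs(d) <= projection_halfwidth
    if keep.sum() < 16 * oversample:
        raise ValueError("too few pixels near the edge for ESF binning")
    dk = d[keep]
    vals = work[keep]
    pitch = 1.0 / oversample
    dmin = dk.min()
    idx = np.floor((dk - dmin) / pitch).astype(np.int64)
    nb = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=nb)
    sums = np.bincount(idx, weights=vals, minlength=nb)
    # trim sparsely populated end bins (projection extremes hold only a
    # corner pixel or two and would dominate the differentiated noise)
    med = np.median(counts[counts > 0])
    adequate = counts >= max(1.0, 0.5 * med)
    first, last = np.argmax(adequate), nb - np.argmax(adequate[::-1]) - 1
    counts = counts[first:last + 1]
    sums = sums[first:last + 1]
    if (counts == 0).any():
        raise ValueError("insufficient samples per ESF bin; reduce "
                         "oversample or enlarge the ROI")
    esf = sums / counts

    lsf = np.zeros_like(esf)
    lsf[1:-1] = 0.5 * (esf[2:] - esf[:-2])
    # the transition sits at projection coordinate d = 0 by construction;
    # search for the LSF peak only near it, not among far-field noise
    center = (0.0 - dmin) / pitch - first
    search = max(1, int(round(center - 8 * oversample))), \
        min(len(lsf), int(round(center + 8 * oversample)))
    peak = search[0] + int(np.argmax(np.abs(lsf[search[0]:search[1]])))
    n = len(lsf)
    half_width = n / 2.0
    i = np.arange(n)
    w = np.where(np.abs(i - peak) <= half_width,
                 0.5 * (1 + np.cos(np.pi * (i - peak) / half_width)), 0.0)
    lsf_w = lsf * w

    spectrum = np.abs(np.fft.rfft(lsf_w))
    if spectrum[0] == 0:
        raise ValueError("degenerate LSF: zero integrated contrast")
    mtf = spectrum / spectrum[0]
    f_cyc = np.fft.rfftfreq(n, d=pitch)  # cycles per physical pixel
    # compensate the known responses of the central-difference derivative
    # (sinc(2 f pitch)) and the ESF bin aperture (sinc(f pitch))
    comp = np.sinc(2 * f_cyc * pitch) * np.sinc(f_cyc * pitch)
    mtf = mtf / np.maximum(comp, 0.2)
    freq = f_cyc / 0.5                   # physical-Nyquist units
    sel = freq <= max_freq + 1e-12
    return TransferCurves(freq=freq[sel], mtf=mtf[sel])


@dataclass(frozen=True)
class Dqe0Result:
    """Zero-frequency DQE from noise binning.

    ``mode`` is ``"absolute"`` when the incident dose was known and
    ``"poisson_relative"`` when DQE(0) is reported relative to an ideal
    Poisson detector (no incident-dose information).
    """

    value: float
    v_infinity: float
    mode: str
    bin_factors: tuple[int, ...]
    v_curve: tuple[float, ...]
    mean_detected_per_pixel: float
    incident_per_pixel: Optional[float] = None

    def __float__(self) -> float:
        return self.value


def _binned_variance(img: np.ndarray, b: int) -> float:
    ny, nx = img.shape
    ny_b, nx_b = ny // b, nx // b
    if ny_b < 2 or nx_b < 2:
        raise ValueError(f"bin factor {b} leaves too few blocks")
    blk = img[:ny_b * b, :nx_b * b].reshape(ny_b, b, nx_b, b).sum(axis=(1, 3))
    return float(np.var(blk, ddof=1))


def dqe0_noise_binning(flood, incident_eps: Optional[float] = None,
                       incident_per_pixel: Optional[float] = None,
                       electron_value: int = 1,
                       exposure_time: Optional[float] = None,
                       bin_factors: Optional[Sequence[int]] = None,
                       plateau_rtol: float = 0.05) -> Dqe0Result:
    """DQE(0) of a uniform flood exposure by the noise-binning method.

    ``flood`` is a movie or a 2-D array of detected counts; arrays are
    divided by ``electron_value`` to get detected electrons per physical
    pixel.  For bin factor b, ``v(b) = Var[b x b block sums] / (b**2 *
    mean)``; the zero-frequency noise ``v_inf`` is the plateau of v at
    large b (largest adjacent pair agreeing within ``plateau_rtol``).

    With incident information (``incident_per_pixel`` electrons, or
    ``incident_eps`` with a movie/``exposure_time``),
    ``DQE(0) = (mean / N_in) / v_inf``; without it the Poisson-relative
    figure ``1 / v_inf`` is returned with ``mode="poisson_relative"``.
    """
    if isinstance(flood, SuperResMovie):
        img = flood.physical_image().astype(np.float64) / flood.electron_value
        if exposure_time is None:
            exposure_time = flood.exposure_time
    else:
        img = np.asarray(flood, dtype=np.float64) / electron_value
    if img.ndim != 2:
        raise ValueError("flood must be 2-D (or a movie)")
    mean = float(img.mean())
    if mean <= 0:
        raise ValueError("flood image has zero mean")

    if bin_factors is None:
        bmax = min(64, min(img.shape) // 16)
        bin_factors = [b for b in (1, 2, 4, 8, 16, 32, 64) if b <= bmax]
    if len(bin_factors) < 2:
        raise ValueError("image too small for noise binning")
    v = [_binned_variance(img, b) / (b * b * mean) for b in bin_factors]

    v_inf = None
    for i in range(len(v) - 1, 0, -1):
        lo, hi = v[i - 1], v[i]
        if abs(hi - lo) / max(abs(hi), abs(lo)) < plateau_rtol:
            v_inf = 0.5 * (lo + hi)
            break
    if v_inf is None or v_inf <= 0:
        raise PlateauError(
            "binned variance did not plateau: illumination is not "
            f"statistically uniform (v(b) = {np.round(v, 4).tolist()})")

    if incident_per_pixel is None and incident_eps is not None:
        if exposure_time is None:
            raise ValueError("incident_eps requires an exposure time")
        incident_per_pixel = incident_eps * exposure_time

    if incident_per_pixel is not None:
        if incident_per_pixel <= 0:
            raise ValueError("incident dose must be positive")
        value = (mean / incident_per_pixel) / v_inf
        mode = "absolute"
    else:
        value = 1.0 / v_inf
        mode = "poisson_relative"
    return Dqe0Result(value=float(value), v_infinity=float(v_inf), mode=mode,
                      bin_factors=tuple(int(b) for b in bin_factors),
                      v_curve=tuple(float(x) for x in v),
                      mean_detected_per_pixel=mean,
                      incident_per_pixel=incident_per_pixel)


def dqe_curve(dqe0: float | Dqe0Result, mtf: TransferCurves,
              nnps: Optional[RadialSpectrum] = None) -> TransferCurves:
    """Compose the DQE curve: DQE(s) = DQE(0) * MTF(s)**2 / NNPS(s).

    ``nnps`` defaults to unity at all frequencies (appropriate for
    counting data with negligible coincidence loss); when supplied it is
    interpolated onto the MTF frequency axis and must cover it.
    """
    d0 = float(dqe0)
    if not 0 <= d0 <= 1.5:
        raise ValueError("dqe0 out of range")
    if nnps is None:
        nnps_vals = np.ones_like(mtf.freq)
        assumed = "unity"
    else:
        if nnps.norm_band is None:
            raise ValueError("NNPS spectrum must be normalized")
        if nnps.freq[-1] < mtf.freq[-1] - 1e-9 or \
                nnps.freq[0] > mtf.freq[0] + max(np.diff(mtf.freq).min(), 1e-9):
            raise ValueError("NNPS frequency axis does not cover the MTF "
                             "axis; resample the spectrum first")
        nnps_vals = np.interp(mtf.freq, nnps.freq, nnps.power)
        if (nnps_vals <= 0).any():
            raise ValueError("NNPS must be positive on the MTF axis")
        assumed = "measured"
    dqe = d0 * mtf.mtf ** 2 / nnps_vals
    return TransferCurves(freq=mtf.freq.copy(), mtf=mtf.mtf.copy(),
                          dqe0=d0, dqe=dqe, nnps_assumed=assumed)


def theoretical_square_pixel_dqe(freq) -> np.ndarray | float:
    """Theoretical maximum DQE of an ideal square-pixel counting detector.

    ``|sinc(f/2)|**2`` with f in physical-Nyquist units: 1 at zero
    frequency, (2/pi)**2 = 0.405 at Nyquist.
    """
    f = np.asarray(freq, dtype=np.float64)
    out = np.sinc(0.5 * f) ** 2
    return float(out) if out.ndim == 0 else out
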