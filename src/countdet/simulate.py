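"""Event-based simulator for an electron-counting direct detector.

The counting mechanism: per physical pixel, time is partitioned into
internal counting windows of length ``a`` seconds.  Electron arrivals are
Poisson; a window records exactly one detected event if at least one
electron arrives in it, so extra arrivals within a window are merged
(coincidence loss) and the expected detected rate at input rate ``x`` is
``(1 - exp(-a*x)) / a``.  Each detected event is localized to a uniformly
random sub-pixel of its physical pixel and recorded with a fixed integer
value (16 by default).  False positives arrive as an independent,
spatially uniform Poisson process.

Two sampling paths produce identical statistics:

* the frame-resolved path draws Poisson arrivals window by window (the
  mechanism itself), assigning windows to output frames by start time;
* the accumulated path (``accumulate=True``) draws the total detected
  count per pixel in one Binomial step and, when ground truth is
  requested, reconstructs merged arrivals exactly from the distribution
  of arrivals in an occupied window.  Use it for long exposures where a
  frame stack would be enormous.

All randomness comes from one ``numpy.random.Generator`` seeded with the
single integer ``seed``; draws occur in a fixed, documented order, so the
same seed gives a bit-identical movie and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .movie import SuperResMovie

__all__ = [
    "DetectorSpec", "Scene", "GroundTruth",
    "SaturationError", "EdgeAngleError",
    "simulate_flat_movie", "simulate_edge_movie", "simulate_beam_off",
    "simulate_reslog_table", "make_edge_scene", "analytic_system_mtf",
]


class SaturationError(ValueError):
    """Input dose rate beyond the detector's usable range (artifact regime)."""


class EdgeAngleError(ValueError):
    """Edge slant outside the regime where the slanted-edge method works."""


@dataclass(frozen=True)
class DetectorSpec:
    """Physical parameters of the simulated counting detector.

    Parameters
    ----------
    a:
        Saturation constant in s*pixel/electron; the internal counting
        window length.  ``1/a`` is the maximum detectable eps.
    false_positive_rate:
        Dark-count events per physical pixel per second.
    psf_sigma:
        Optional Gaussian blur (sigma, physical pixels) applied to the
        illumination scene before counting.
    electron_value:
        Counts recorded per detected event.
    subpixels_per_axis:
        Super-resolution subdivision per physical-pixel axis.
    frame_period:
        Seconds per output movie frame (default 1/60 s; 16.6 ms is an
        accepted alternative).
    saturation_input_eps:
        Input rate above which the simulation refuses (the real camera
        produces readout artifacts, not data, beyond this).
    """

    a: float = 0.007
    false_positive_rate: float = 2.86e-6
    psf_sigma: float = 0.0
    electron_value: int = 16
    subpixels_per_axis: int = 2
    frame_period: float = 1.0 / 60.0
    saturation_input_eps: float = 80.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be >= 0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.electron_value < 1:
            raise ValueError("electron_value must be >= 1")
        if self.subpixels_per_axis < 1:
            raise ValueError("subpixels_per_axis must be >= 1")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be > 0")


@dataclass
class Scene:
    """Illumination scene on the physical-pixel grid.

    ``intensity_map`` is relative illumination in [0, 1];
    ``base_input_eps`` is the input dose rate x (electrons per physical
    pixel per second) where intensity is 1.0.
    """

    shape: tuple[int, int]
    intensity_map: np.ndarray
    base_input_eps: float

    def __post_init__(self) -> None:
        self.intensity_map = np.asarray(self.intensity_map, dtype=np.float64)
        if tuple(self.shape) != self.intensity_map.shape:
            raise ValueError("shape does not match intensity_map")
        if self.intensity_map.min() < 0 or self.intensity_map.max() > 1 + 1e-12:
            raise ValueError("intensity_map values must lie in [0, 1]")
        if self.base_input_eps < 0:
            raise ValueError("base_input_eps must be >= 0")

    @classmethod
    def uniform(cls, shape: tuple[int, int], input_eps: float) -> "Scene":
        return cls(tuple(shape), np.ones(shape), input_eps)

    def rate_map(self) -> np.ndarray:
        """Input eps per physical pixel."""
        return self.intensity_map * self.base_input_eps


@dataclass
class GroundTruth:
    """Per-physical-pixel electron accounting for a simulated movie.

    Invariant: ``detected_electrons + merged_events == emitted_electrons``
    for every pixel, every run.  False positives are counted separately
    (they are not electrons).
    """

    emitted_electrons: np.ndarray
    detected_electrons: np.ndarray
    merged_events: np.ndarray
    false_positives: np.ndarray
    seed: int

    def check(self) -> None:
        if not np.array_equal(self.detected_electrons + self.merged_events,
                              self.emitted_electrons):
            raise AssertionError("electron conservation violated")
        for name in ("emitted_electrons", "detected_electrons",
                     "merged_events", "false_positives"):
            if (getattr(self, name) < 0).any():
                raise AssertionError(f"{name} has negative counts")


# ---------------------------------------------------------------------------
# internal kernels

def _window_layout(duration: float, a: float) -> tuple[int, float]:
    """Number of full counting windows in [0, duration) and the remainder."""
    n_full = int(math.floor(duration / a + 1e-9))
    rem = duration - n_full * a
    if rem < 1e-9 * max(duration, a):
        rem = 0.0
    return n_full, rem


def _place_subpixels(events: np.ndarray, sf: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Distribute per-pixel event counts uniformly over sf*sf sub-pixels.

    Sequential binomial splitting of a multinomial draw; returns the
    super-resolution count grid.
    """
    ny, nx = events.shape
    if sf == 1:
        return events.astype(np.uint32)
    ncat = sf * sf
    out = np.empty((ny * sf, nx * sf), dtype=np.uint32)
    remaining = events.astype(np.int64)
    for j in range(ncat):
        if j < ncat - 1:
            c = rng.binomial(remaining, 1.0 / (ncat - j))
        else:
            c = remaining
        remaining = remaining - c
        dy, dx = divmod(j, sf)
        out[dy::sf, dx::sf] = c
    return out


def _merged_arrivals(k: np.ndarray, x: np.ndarray, window: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Extra (merged) arrivals in k occupied windows per pixel, exactly.

    Given that a window of length ``window`` at rate ``x`` holds at least
    one arrival, the first arrival time is a truncated exponential and the
    remaining arrivals are Poisson over the rest of the window.  Sampling
    that way per occupied window reproduces the zero-truncated Poisson
    arrival count without evaluating its quantile function.
    """
    k = k.astype(np.int64)
    total = int(k.sum())
    merged = np.zeros(k.shape, dtype=np.int64)
    if total == 0:
        return merged
    idx = np.repeat(np.arange(k.size), k.ravel())
    xr = np.broadcast_to(x, k.shape).ravel()[idx]
    lam = xr * window
    u = rng.random(total)
    # first-arrival time within the window, conditioned on >=1 arrival
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = -np.log1p(-u * (-np.expm1(-lam))) / xr
    t1 = np.where(xr > 0, t1, 0.0)
    extras = rng.poisson(xr * (window - t1))
    np.add.at(merged.ravel(), idx, extras)
    return merged


def _frame_window_counts(duration: float, a: float,
                         frame_period: float) -> tuple[np.ndarray, int, float]:
    """Full windows per output frame (assignment by window start time)."""
    n_full, rem = _window_layout(duration, a)
    n_frames = max(1, int(math.ceil(duration / frame_period - 1e-9)))
    starts = np.arange(n_full) * a
    frame_of = np.minimum((starts / frame_period).astype(np.int64),
                          n_frames - 1)
    counts = np.bincount(frame_of, minlength=n_frames)
    return counts, n_frames, rem


def _simulate_counting(spec: DetectorSpec, scene: Scene, duration: float,
                       seed: int, accumulate: bool,
                       ground_truth: bool):
    """Shared counting kernel.  Returns (movie, GroundTruth or None)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    x = scene.rate_map()
    if x.max() > spec.saturation_input_eps:
        raise SaturationError(
            f"input dose rate {x.max():.3g} eps exceeds the saturation "
            f"threshold of {spec.saturation_input_eps:g} eps; the detector "
            "produces readout artifacts, not data, in this regime")
    rng = np.random.default_rng(seed)
    ny, nx = scene.shape
    sf = spec.subpixels_per_axis
    lam = x * spec.a  # arrivals per full window
    p = -np.expm1(-lam)

    detected_total = np.zeros((ny, nx), dtype=np.int64)
    emitted_total = np.zeros((ny, nx), dtype=np.int64) if ground_truth else None
    fp_total = np.zeros((ny, nx), dtype=np.int64)

    if accumulate:
        n_full, rem = _window_layout(duration, spec.a)
        k = rng.binomial(n_full, p) if n_full > 0 else np.zeros_like(
            detected_total)
        merged = None
        if ground_truth:
            merged = _merged_arrivals(k, x, spec.a, rng)
        if rem > 0:
            p_rem = -np.expm1(-x * rem)
            k_rem = rng.binomial(1, p_rem)
            if ground_truth:
                merged = merged + _merged_arrivals(k_rem, x, rem, rng)
            k = k + k_rem
        detected_total[:] = k
        if ground_truth:
            emitted_total[:] = k + merged
        fp = rng.poisson(spec.false_positive_rate * duration,
                         size=(ny, nx))
        fp_total[:] = fp
        frame_events = [(detected_total + fp_total)]
        n_frames = 1
    else:
        if duration < spec.frame_period - 1e-12:
            raise ValueError("duration must be at least one frame period")
        counts, n_frames, rem = _frame_window_counts(
            duration, spec.a, spec.frame_period)
        frame_events = []
        for f in range(n_frames):
            k_f = np.zeros((ny, nx), dtype=np.int64)
            for _ in range(int(counts[f])):
                arrivals = rng.poisson(lam)
                k_f += arrivals > 0
                if ground_truth:
                    emitted_total += arrivals
            if f == n_frames - 1 and rem > 0:
                arrivals = rng.poisson(x * rem)
                k_f += arrivals > 0
                if ground_truth:
                    emitted_total += arrivals
            cover = min((f + 1) * spec.frame_period, duration) \
                - f * spec.frame_period
            fp_f = rng.poisson(spec.false_positive_rate * cover,
                               size=(ny, nx))
            detected_total += k_f
            fp_total += fp_f
            frame_events.append(k_f + fp_f)

    frames = np.empty((n_frames, ny * sf, nx * sf), dtype=np.uint16)
    for f, ev in enumerate(frame_events):
        sub = _place_subpixels(ev, sf, rng)
        vals = sub * spec.electron_value
        if vals.max(initial=0) > np.iinfo(np.uint16).max:
            frames = frames.astype(np.uint32)
        frames[f] = vals

    movie = SuperResMovie(
        data=frames, frame_period=spec.frame_period, exposure_time=duration,
        superres_factor=sf, electron_value=spec.electron_value,
        extra={"seed": seed},
    )
    gt = None
    if ground_truth:
        gt = GroundTruth(
            emitted_electrons=emitted_total,
            detected_electrons=detected_total,
            merged_events=emitted_total - detected_total,
            false_positives=fp_total,
            seed=seed,
        )
    return movie, gt


# ---------------------------------------------------------------------------
# public operations

def simulate_flat_movie(spec: DetectorSpec, scene: Scene, duration: float,
                        seed: int, accumulate: bool = False,
                        ground_truth: bool = True,
                        ) -> tuple[SuperResMovie, Optional[GroundTruth]]:
    """Simulate a (flood or arbitrary-scene) counted movie.

    Returns the super-resolution movie and, when ``ground_truth`` is
    true, the per-pixel electron accounting.  With ``accumulate=True``
    the whole exposure is summed into a single output frame, which is the
    economical choice for long flood exposures.
    """
    if not accumulate and duration < spec.frame_period - 1e-12:
        raise ValueError("duration must be at least one frame period")
    return _simulate_counting(spec, scene, duration, seed,
                              accumulate=accumulate,
                              ground_truth=ground_truth)


def _gauss_step_integral(z: np.ndarray, sigma: float) -> np.ndarray:
    """Antiderivative of the Gaussian-blurred unit step: F' = Phi(z/sigma)."""
    if sigma <= 0:
        return np.maximum(z, 0.0)
    from scipy.stats import norm
    return z * norm.cdf(z / sigma) + sigma * norm.pdf(z / sigma)


def make_edge_scene(shape: tuple[int, int], edge_angle: float,
                    edge_offset: float, base_input_eps: float,
                    psf_sigma: float = 0.0,
                    bright_side: str = "left") -> Scene:
    """Pixel-integrated slanted step edge.

    The edge is a straight line tilted ``edge_angle`` degrees from the
    image y axis, crossing ``x = nx/2 + edge_offset`` at the central row.
    Pixel values are the exact integral over the pixel of the step
    convolved with a Gaussian PSF of ``psf_sigma`` (physical pixels); the
    y extent of each pixel is handled by 4-point sub-row averaging, the
    x extent analytically.
    """
    ny, nx = shape
    theta = math.radians(edge_angle)
    sigma_x = psf_sigma / abs(math.cos(theta)) if psf_sigma > 0 else 0.0
    xc = np.arange(nx) + 0.5
    suby = np.array([-0.375, -0.125, 0.125, 0.375])
    intensity = np.zeros((ny, nx))
    x0 = nx / 2.0 + edge_offset
    for dy in suby:
        yrow = np.arange(ny) + 0.5 + dy
        xe = x0 + math.tan(theta) * (yrow - ny / 2.0)
        # bright-left step: intensity(u) = Phi((xe - u)/sigma)
        hi = _gauss_step_integral(xe[:, None] - (xc[None, :] - 0.5), sigma_x)
        lo = _gauss_step_integral(xe[:, None] - (xc[None, :] + 0.5), sigma_x)
        intensity += hi - lo
    intensity /= len(suby)
    if bright_side == "right":
        intensity = 1.0 - intensity
    elif bright_side != "left":
        raise ValueError("bright_side must be 'left' or 'right'")
    return Scene((ny, nx), np.clip(intensity, 0.0, 1.0), base_input_eps)


def analytic_system_mtf(freq: np.ndarray, psf_sigma: float) -> np.ndarray:
    """True system MTF: Gaussian PSF times physical-pixel aperture.

    ``freq`` is in units of physical Nyquist (1.0 = 0.5 cycles per
    physical pixel); ``psf_sigma`` in physical pixels.
    """
    f = np.asarray(freq, dtype=float)
    cyc = 0.5 * f  # cycles per physical pixel
    return np.exp(-2 * np.pi ** 2 * psf_sigma ** 2 * cyc ** 2) \
        * np.abs(np.sinc(cyc))


def simulate_edge_movie(spec: DetectorSpec, edge_angle: float,
                        edge_offset: float, base_input_eps: float,
                        duration: float, seed: int,
                        shape: tuple[int, int] = (256, 256),
                        accumulate: bool = False,
                        bright_side: str = "left") -> SuperResMovie:
    """Simulate a counted movie of a slanted straight edge (beamstop-style).

    The true system MTF (Gaussian PSF x pixel aperture) is recorded in
    ``movie.extra`` for recovery tests.
    """
    if not (1.0 <= abs(edge_angle) <= 15.0):
        raise EdgeAngleError(
            f"edge angle {edge_angle:g} deg is outside the slanted-edge "
            "regime (1-15 deg): edge too steep/shallow")
    scene = make_edge_scene(shape, edge_angle, edge_offset, base_input_eps,
                            psf_sigma=spec.psf_sigma, bright_side=bright_side)
    movie, _ = _simulate_counting(spec, scene, duration, seed,
                                  accumulate=accumulate, ground_truth=False)
    ftrue = np.linspace(0.0, 2.0, 201)
    movie.extra.update({
        "edge_angle": edge_angle,
        "edge_offset": edge_offset,
        "psf_sigma": spec.psf_sigma,
        "bright_side": bright_side,
        "true_mtf_freq": ftrue,
        "true_mtf": analytic_system_mtf(ftrue, spec.psf_sigma),
    })
    return movie


def simulate_beam_off(spec: DetectorSpec, shape: tuple[int, int],
                      duration: float, seed: int,
                      accumulate: bool = True) -> SuperResMovie:
    """Simulate a beam-valve-closed acquisition: false positives only.

    Events are drawn one by one (they are sparse), assigned uniform
    pixels, sub-pixels and times.  By default the output is a single
    accumulated frame; pass ``accumulate=False`` for a frame-resolved
    stack (the array is then n_frames x super-res shape).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    ny, nx = shape
    if ny < 1 or nx < 1:
        raise ValueError("shape must be positive")
    rng = np.random.default_rng(seed)
    sf = spec.subpixels_per_axis
    n_events = rng.poisson(spec.false_positive_rate * ny * nx * duration)
    n_frames = 1 if accumulate else max(
        1, int(math.ceil(duration / spec.frame_period - 1e-9)))
    data = np.zeros((n_frames, ny * sf, nx * sf), dtype=np.uint16)
    if n_events > 0:
        iy = rng.integers(0, ny * sf, n_events)
        ix = rng.integers(0, nx * sf, n_events)
        if accumulate:
            fr = np.zeros(n_events, dtype=np.int64)
        else:
            t = rng.uniform(0.0, duration, n_events)
            fr = np.minimum((t / spec.frame_period).astype(np.int64),
                            n_frames - 1)
        np.add.at(data, (fr, iy, ix), spec.electron_value)
    return SuperResMovie(
        data=data, frame_period=spec.frame_period, exposure_time=duration,
        superres_factor=sf, electron_value=spec.electron_value,
        extra={"seed": seed, "beam_off": True},
    )


def simulate_reslog_table(slope: float, intercept: float,
                          particle_counts, noise_sd: float,
                          transform: str = "reciprocal",
                          seed: int = 0) -> pd.DataFrame:
    """Generate a (particle count, resolution) table from a known line.

    ``transform(resolution) = intercept + slope*log10(N) + noise`` with
    Gaussian noise of sd ``noise_sd``; the transformed values are mapped
    back to Angstrom with the inverse transform.
    """
    from .reslog import get_transform
    if not (math.isfinite(slope) and math.isfinite(intercept)):
        raise ValueError("slope and intercept must be finite")
    n = np.asarray(particle_counts, dtype=np.float64)
    if (n < 1).any():
        raise ValueError("particle counts must be >= 1")
    tr = get_transform(transform)
    rng = np.random.default_rng(seed)
    t = intercept + slope * np.log10(n)
    if noise_sd > 0:
        t = t + rng.normal(0.0, noise_sd, size=n.shape)
    if not tr.invertible_at(t).all():
        raise ValueError(
            f"transform {transform!r} is not invertible on generated "
            "values; adjust slope/intercept/noise")
    res = tr.inverse(t)
    return pd.DataFrame({"n_particles": n.astype(np.int64),
                         "resolution_angstrom": res})
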