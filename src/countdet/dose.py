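"""Coincidence-loss dose-response modelling and exposure planning.

The dose response of a counting detector is ``y = (1 - exp(-a*x)) / a``
where ``x`` is the input dose rate and ``y`` the detected (output) dose
rate, both in electrons per physical pixel per second (eps), and ``a`` is
the single saturation constant (s*pixel/electron).  ``1/a`` is the
supremum of the detectable rate.  Coincidence loss is
``CL(x) = 1 - y(x)/x`` with ``CL(0) = 0`` by continuity.

The fit is least squares in detected-rate space via bounded 1-D
minimization with a fixed bracket, so it is deterministic given the data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .movie import SuperResMovie
from .simulate import SaturationError

__all__ = [
    "DosePair", "DoseResponseModel", "MagSeriesPoint", "ExposurePlan",
    "intensity_to_detected_eps", "build_dose_ladder", "fit_dose_response",
    "predict_detected", "invert_detected", "coincidence_loss",
    "saturation_limit", "plan_exposure", "specimen_dose_rate",
    "false_positive_percent", "read_dose_pairs", "write_dose_pairs",
    "read_mag_series",
]

_FIT_BRACKET = (1e-6, 1.0)


@dataclass(frozen=True)
class DosePair:
    """One (input, detected) dose-rate measurement, both in eps."""

    input_eps: float
    detected_eps: float

    def __post_init__(self) -> None:
        if self.input_eps <= 0:
            raise ValueError("input_eps must be > 0")
        if not 0 < self.detected_eps <= self.input_eps * (1 + 1e-9):
            raise ValueError("detected_eps must lie in (0, input_eps]")


@dataclass(frozen=True)
class DoseResponseModel:
    """Fitted coincidence-loss model: the constant a plus fit diagnostics."""

    a: float
    residual_rms: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")


@dataclass(frozen=True)
class MagSeriesPoint:
    """Flood measurement at one magnification under constant illumination."""

    magnification: float
    pixel_size: float  # Angstrom per physical pixel
    mean_detected_eps: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.mean_detected_eps < 0:
            raise ValueError("mean_detected_eps must be >= 0")


@dataclass(frozen=True)
class ExposurePlan:
    exposure_time: float  # seconds
    n_frames: int
    achieved_dose: float  # e-/A^2


def intensity_to_detected_eps(movie: SuperResMovie) -> float:
    """Detected dose rate (eps, per physical pixel) from a counted movie.

    Mean super-resolution pixel intensity per second, divided by the
    per-event value (16) to get electrons, times the sub-pixels per
    physical pixel (4), i.e. electrons per *physical* pixel per second.
    """
    if movie.n_frames < 1:
        raise ValueError("movie has no frames")
    if movie.exposure_time <= 0:
        raise ValueError("zero exposure time")
    mean_intensity = movie.data.sum(dtype=np.float64) / (
        movie.data.shape[1] * movie.data.shape[2])
    per_second = mean_intensity / movie.exposure_time
    return per_second / movie.electron_value * movie.superres_factor ** 2


def build_dose_ladder(series: Sequence[MagSeriesPoint]) -> list[DosePair]:
    """Input-dose ladder from a constant-illumination magnification series.

    The point with the smallest pixel size (highest magnification, lowest
    per-pixel flux) is the anchor, assumed to have zero coincidence loss:
    its input rate equals its detected rate.  With the specimen-plane flux
    held constant, the per-pixel input rate scales with the pixel area, so
    ``input_m = input_anchor * (p_m / p_anchor)**2``.
    """
    if len(series) < 1:
        raise ValueError("need at least one magnification point")
    mags = [p.magnification for p in series]
    if len(set(mags)) != len(mags):
        raise ValueError("duplicate magnifications in series")
    anchor = min(series, key=lambda p: p.pixel_size)
    order = sorted(series, key=lambda p: p.pixel_size)
    detected = [p.mean_detected_eps for p in order]
    if any(d2 < d1 for d1, d2 in zip(detected, detected[1:])):
        warnings.warn("detected rate is not monotone in pixel size; "
                      "check the magnification series", stacklevel=2)
    ladder = []
    for p in series:
        x = anchor.mean_detected_eps * (p.pixel_size / anchor.pixel_size) ** 2
        ladder.append(DosePair(input_eps=x, detected_eps=p.mean_detected_eps))
    return ladder


def _as_arrays(pairs: Iterable) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for p in pairs:
        if isinstance(p, DosePair):
            xs.append(p.input_eps)
            ys.append(p.detected_eps)
        else:
            x, y = p
            xs.append(float(x))
            ys.append(float(y))
    return np.asarray(xs), np.asarray(ys)


def fit_dose_response(pairs: Iterable) -> DoseResponseModel:
    """Least-squares fit of the saturation constant a.

    Minimizes ``sum (y_i - (1-exp(-a x_i))/a)**2`` over a fixed bracket
    ``[1e-6, 1]`` with tight tolerance, so the result is deterministic.
    """
    x, y = _as_arrays(pairs)
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise ValueError("need >= 2 pairs with distinct input rates")

    def sse(a: float) -> float:
        return float(np.sum((y - -np.expm1(-a * x) / a) ** 2))

    res = minimize_scalar(sse, bounds=_FIT_BRACKET, method="bounded",
                          options={"xatol": 1e-13})
    a = float(res.x)
    if a < _FIT_BRACKET[0] * 2:
        warnings.warn("fitted a is at the lower bound: no measurable "
                      "coincidence loss in these data", stacklevel=2)
    rms = math.sqrt(sse(a) / len(x))
    return DoseResponseModel(a=a, residual_rms=rms, n_points=len(x))


def predict_detected(model: DoseResponseModel, x) -> np.ndarray | float:
    """Detected rate y = (1 - exp(-a x)) / a for input rate x (eps)."""
    x = np.asarray(x, dtype=np.float64)
    if (x < 0).any():
        raise ValueError("input rate must be >= 0")
    y = -np.expm1(-model.a * x) / model.a
    return float(y) if y.ndim == 0 else y


def invert_detected(model: DoseResponseModel, y) -> np.ndarray | float:
    """Input rate x = -ln(1 - a y)/a for detected rate y (closed form)."""
    y = np.asarray(y, dtype=np.float64)
    if (y < 0).any():
        raise ValueError("detected rate must be >= 0")
    if (y >= 1.0 / model.a).any():
        raise SaturationError(
            f"detected rate >= saturation limit 1/a = {1/model.a:.4g} eps: "
            "above saturation, not invertible")
    x = -np.log1p(-model.a * y) / model.a
    return float(x) if x.ndim == 0 else x


def coincidence_loss(model: DoseResponseModel, x) -> np.ndarray | float:
    """Coincidence-loss fraction CL(x) = 1 - y(x)/x, with CL(0) = 0."""
    x = np.asarray(x, dtype=np.float64)
    if (x < 0).any():
        raise ValueError("input rate must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        cl = np.where(x > 0, 1.0 + np.expm1(-model.a * x) / (model.a * x),
                      0.0)
    return float(cl) if cl.ndim == 0 else cl


def saturation_limit(model: DoseResponseModel) -> float:
    """Supremum of the detectable rate, 1/a (eps)."""
    return 1.0 / model.a


def plan_exposure(target_dose: float, pixel_size: float, detected_eps: float,
                  frame_rate: float = 60.0) -> ExposurePlan:
    """Exposure time and frame count to reach a target specimen dose.

    ``target_dose`` in e-/A^2, ``pixel_size`` in A/physical pixel,
    ``detected_eps`` per physical pixel, ``frame_rate`` in frames/s.
    """
    for name, v in (("target_dose", target_dose), ("pixel_size", pixel_size),
                    ("detected_eps", detected_eps),
                    ("frame_rate", frame_rate)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    t = target_dose * pixel_size ** 2 / detected_eps
    n_frames = int(round(t * frame_rate))
    achieved = (n_frames / frame_rate) * detected_eps / pixel_size ** 2
    return ExposurePlan(exposure_time=t, n_frames=n_frames,
                        achieved_dose=achieved)


def specimen_dose_rate(detected_eps: float, pixel_size: float) -> float:
    """Dose rate on the specimen (e-/A^2/s) from per-pixel rate."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return detected_eps / pixel_size ** 2


def false_positive_percent(rate: float, dose_rate_eps: float) -> float:
    """False positives as a percentage of the signal dose rate."""
    if dose_rate_eps <= 0:
        raise ValueError("dose_rate_eps must be > 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return 100.0 * rate / dose_rate_eps


# ---------------------------------------------------------------------------
# CSV interfaces

def read_dose_pairs(path) -> list[DosePair]:
    """CSV with columns input_eps, detected_eps."""
    df = pd.read_csv(path)
    return [DosePair(float(r.input_eps), float(r.detected_eps))
            for r in df.itertuples()]


def write_dose_pairs(pairs: Sequence[DosePair], path) -> None:
    pd.DataFrame({
        "input_eps": [p.input_eps for p in pairs],
        "detected_eps": [p.detected_eps for p in pairs],
    }).to_csv(path, index=False)


def read_mag_series(path) -> list[MagSeriesPoint]:
    """CSV with columns magnification, pixel_size, mean_detected_eps."""
    df = pd.read_csv(path)
    return [MagSeriesPoint(float(r.magnification), float(r.pixel_size),
                           float(r.mean_detected_eps))
            for r in df.itertuples()]
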