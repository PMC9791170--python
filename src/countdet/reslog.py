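"""ResLog analysis: resolution versus the logarithm of particle count.

Single-particle reconstruction resolution improves linearly with the
logarithm of the number of particles over a wide regime.  The slope of a
ResLog line reflects per-particle information content (image quality);
the intercept — the extrapolated resolution from a single particle —
reflects the average accuracy of particle alignment.

Published ResLog slopes are only comparable under a stated resolution
transform, so the transform is a mandatory, recorded parameter.  The
default regresses reciprocal resolution (1/Angstrom) on log10(N);
identity (Angstrom) and reciprocal-squared (1/Angstrom^2, Rosenthal-
Henderson-style spatial-frequency-squared axis) are also available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResLogPoint", "ResLogFit", "Transform", "TRANSFORMS", "get_transform",
    "fit_reslog", "slope_percent_change", "particles_for_resolution",
    "particle_factor", "read_reslog_points",
]


@dataclass(frozen=True)
class Transform:
    """Invertible map applied to resolution (Angstrom) before the fit."""

    name: str
    forward: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]

    def invertible_at(self, transformed: np.ndarray) -> np.ndarray:
        """Mask of transformed values that map back to a positive Angstrom."""
        t = np.asarray(transformed, dtype=float)
        if self.name == "identity":
            return t > 0
        return t > 0  # reciprocal and reciprocal-squared need t > 0 too


TRANSFORMS = {
    "identity": Transform("identity", lambda r: np.asarray(r, float),
                          lambda t: np.asarray(t, float)),
    "reciprocal": Transform("reciprocal", lambda r: 1.0 / np.asarray(r, float),
                            lambda t: 1.0 / np.asarray(t, float)),
    "reciprocal_squared": Transform(
        "reciprocal_squared", lambda r: 1.0 / np.asarray(r, float) ** 2,
        lambda t: 1.0 / np.sqrt(np.asarray(t, float))),
}


def get_transform(name: str | Transform) -> Transform:
    if isinstance(name, Transform):
        return name
    try:
        return TRANSFORMS[name]
    except KeyError:
        raise ValueError(f"unknown transform {name!r}; choose from "
                         f"{sorted(TRANSFORMS)}") from None


@dataclass(frozen=True)
class ResLogPoint:
    n_particles: int
    resolution: float  # Angstrom

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")


@dataclass(frozen=True)
class ResLogFit:
    """OLS fit of transform(resolution) on log10(n_particles)."""

    slope: float
    intercept: float
    transform: str
    r_squared: float
    n_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValueError("fit parameters must be finite")

    def predict_resolution(self, n_particles) -> np.ndarray | float:
        tr = get_transform(self.transform)
        t = self.intercept + self.slope * np.log10(
            np.asarray(n_particles, dtype=float))
        res = tr.inverse(t)
        return float(res) if np.ndim(res) == 0 else res


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        n = points["n_particles"].to_numpy(dtype=float)
        r = points["resolution_angstrom"].to_numpy(dtype=float)
        return n, r
    ns, rs = [], []
    for p in points:
        if isinstance(p, ResLogPoint):
            ns.append(p.n_particles)
            rs.append(p.resolution)
        else:
            n, r = p
            ns.append(float(n))
            rs.append(float(r))
    return np.asarray(ns, float), np.asarray(rs, float)


def fit_reslog(points: Iterable | pd.DataFrame,
               transform: str = "reciprocal") -> ResLogFit:
    """Ordinary least squares of transform(resolution) on log10(N)."""
    n, r = _as_points(points)
    if (n < 1).any():
        raise ValueError("n_particles must be >= 1")
    if (r <= 0).any():
        raise ValueError("resolutions must be positive")
    if len(np.unique(n)) < 2:
        raise ValueError("need >= 2 points with distinct particle counts")
    tr = get_transform(transform)
    x = np.log10(n)
    t = tr.forward(r)
    slope, intercept = np.polyfit(x, t, 1)
    pred = intercept + slope * x
    ss_res = float(np.sum((t - pred) ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ResLogFit(slope=float(slope), intercept=float(intercept),
                     transform=tr.name, r_squared=r2,
                     n_range=(float(n.min()), float(n.max())))


def slope_percent_change(fit_ref: ResLogFit, fit_other: ResLogFit) -> float:
    """Percent slope degradation of ``fit_other`` relative to ``fit_ref``."""
    if fit_ref.transform != fit_other.transform:
        raise ValueError("fits use different transforms; slopes are not "
                         "comparable")
    if fit_ref.slope == 0:
        raise ValueError("reference slope is zero")
    return 100.0 * (fit_ref.slope - fit_other.slope) / fit_ref.slope


def particles_for_resolution(fit: ResLogFit, target_resolution: float,
                             extrapolation_factor: float = 10.0) -> float:
    """Particles needed to reach a target resolution under the fitted line.

    ``n = 10**((transform(target) - intercept) / slope)``.  Warns (does not
    refuse) when the answer lies more than ``extrapolation_factor`` beyond
    the fitted data range.
    """
    if target_resolution <= 0:
        raise ValueError("target resolution must be positive")
    if fit.slope == 0:
        raise ValueError("unreachable: zero slope, resolution does not "
                         "change with particle count")
    tr = get_transform(fit.transform)
    t_target = float(tr.forward(np.asarray(target_resolution)))
    log_n = (t_target - fit.intercept) / fit.slope
    n = 10.0 ** log_n
    lo, hi = fit.n_range
    if n > hi * extrapolation_factor or n < lo / extrapolation_factor:
        warnings.warn(
            f"target {target_resolution:g} A needs n = {n:.3g}, more than "
            f"{extrapolation_factor:g}x outside the fitted range "
            f"[{lo:g}, {hi:g}]; extrapolation is unreliable", stacklevel=2)
    if n < 1:
        warnings.warn("projection below one particle; the target is "
                      "effectively reached by the intercept", stacklevel=2)
    return float(n)


def particle_factor(fit_a: ResLogFit, fit_b: ResLogFit,
                    target_resolution: float) -> float:
    """How many more particles fit_b needs than fit_a at the same target."""
    n_a = particles_for_resolution(fit_a, target_resolution)
    n_b = particles_for_resolution(fit_b, target_resolution)
    return n_b / n_a


def read_reslog_points(path) -> pd.DataFrame:
    """CSV with columns n_particles, resolution_angstrom."""
    df = pd.read_csv(path)
    missing = {"n_particles", "resolution_angstrom"} - set(df.columns)
    if missing:
        raise ValueError(f"CSV missing columns: {sorted(missing)}")
    return df
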