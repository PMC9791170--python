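"""End-to-end characterization pipeline.

Runs the stages of a detector characterization — dose ladder and
coincidence-loss fit, noise power spectra, beam-off false-positive rate,
slanted-edge MTF, noise-binning DQE(0), DQE curve, and optional ResLog
fits — from a single config dict, on simulated or on-disk inputs, and
emits one JSON-serializable report with every intermediate.

Determinism: all stage seeds are derived from the single config seed in a
fixed order, so the same config yields a bit-identical report.  Per-stage
wall times go to the log only (informational), never into the report.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dose import (DosePair, build_dose_ladder, coincidence_loss,
                   fit_dose_response, intensity_to_detected_eps,
                   invert_detected, MagSeriesPoint)
from .io import read_movie
from .movie import SuperResMovie
from .reslog import fit_reslog, slope_percent_change
from .simulate import (DetectorSpec, Scene, simulate_beam_off,
                       simulate_edge_movie, simulate_flat_movie)
from .spectral import (false_positive_rate_estimate, normalize_nps,
                       nps_coincidence_loss, nps_suppression,
                       radial_power_spectrum)
from .transfer import dqe0_noise_binning, dqe_curve, edge_to_mtf, fit_edge

__all__ = ["run_characterization"]

log = logging.getLogger("countdet.pipeline")

_STAGES = ("dose_response", "nps", "beam_off", "mtf", "dqe0", "dqe_curve",
           "reslog")


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {name: int(s) & 0x7FFFFFFF for name, s in zip(_STAGES, state)}


def _load_or_none(entry) -> Optional[SuperResMovie]:
    if entry and "path" in entry:
        movie, _ = read_movie(entry["path"])
        return movie
    return None


def run_characterization(config: dict, out_dir=None) -> dict:
    """Execute the characterization pipeline described by ``config``.

    Required: ``config["seed"]``.  Optional sections ``detector``,
    ``dose_response``, ``nps``, ``beam_off``, ``edge``, ``dqe0`` and
    ``reslog`` enable their stages; a stage without inputs is marked
    ``"skipped"`` in the report.  Each simulated section takes
    ``input_eps``, ``shape`` and ``duration``.  When ``out_dir`` is given,
    the report JSON and curve CSVs are written there.
    """
    if "seed" not in config:
        raise ValueError("config requires a 'seed' for all random stages")
    seed = int(config["seed"])
    seeds = _stage_seeds(seed)
    spec = DetectorSpec(**config.get("detector", {}))

    from . import __version__ as pkg_version
    report: dict = {
        "versions": {"countdet": pkg_version, "numpy": np.__version__},
        "seed": seed,
        "stage_seeds": seeds,
        "detector": {
            "a": spec.a, "false_positive_rate": spec.false_positive_rate,
            "psf_sigma": spec.psf_sigma, "electron_value": spec.electron_value,
            "subpixels_per_axis": spec.subpixels_per_axis,
            "frame_period": spec.frame_period,
            "saturation_input_eps": spec.saturation_input_eps,
        },
        "stages": {},
    }

    def run_stage(name, fn, enabled):
        t0 = time.perf_counter()
        if not enabled:
            report["stages"][name] = {"status": "skipped",
                                      "reason": "no inputs configured"}
            log.info("stage %-13s skipped", name)
            return None
        try:
            result = fn()
        except Exception as exc:
            report["stages"][name] = {"status": "failed",
                                      "reason": f"{type(exc).__name__}: {exc}"}
            log.error("stage %-13s failed: %s", name, exc)
            return None
        result["status"] = "complete"
        report["stages"][name] = result
        log.info("stage %-13s complete in %.2f s", name,
                 time.perf_counter() - t0)
        return result

    # ---- dose response -----------------------------------------------
    cfg = config.get("dose_response")
    model = None

    def dose_stage():
        nonlocal model
        pairs: list[DosePair] = []
        if "pairs" in cfg:
            pairs = [DosePair(float(x), float(y)) for x, y in cfg["pairs"]]
        elif "mag_series" in cfg:
            series = [MagSeriesPoint(*row) for row in cfg["mag_series"]]
            pairs = build_dose_ladder(series)
        else:
            shape = tuple(cfg.get("shape", (256, 256)))
            duration = float(cfg.get("duration", 8.0))
            for i, x in enumerate(cfg["input_eps"]):
                movie, _ = simulate_flat_movie(
                    spec, Scene.uniform(shape, float(x)), duration,
                    seed=seeds["dose_response"] + i, accumulate=True,
                    ground_truth=False)
                pairs.append(DosePair(float(x),
                                      intensity_to_detected_eps(movie)))
        model = fit_dose_response(pairs)
        return {
            "pairs": [[p.input_eps, p.detected_eps] for p in pairs],
            "a": model.a, "residual_rms_eps": model.residual_rms,
            "n_points": model.n_points, "saturation_eps": 1.0 / model.a,
            "coincidence_loss_percent": {
                str(p.input_eps): 100.0 * coincidence_loss(model, p.input_eps)
                for p in pairs},
        }

    run_stage("dose_response", dose_stage, cfg is not None)

    # ---- noise power spectra ----------------------------------------
    cfg = config.get("nps")
    nps_curves: dict[str, pd.DataFrame] = {}

    def nps_stage():
        out = {"rates": {}}
        movies: list[tuple[str, SuperResMovie]] = []
        if "path" in cfg:
            movies.append((cfg.get("label", "file"), _load_or_none(cfg)))
        else:
            shape = tuple(cfg.get("shape", (1024, 1024)))
            duration = float(cfg.get("duration", 1.0 / 60.0))
            for i, x in enumerate(cfg["input_eps"]):
                movie, _ = simulate_flat_movie(
                    spec, Scene.uniform(shape, float(x)), duration,
                    seed=seeds["nps"] + i, accumulate=True,
                    ground_truth=False)
                movies.append((str(x), movie))
        for label, movie in movies:
            spectrum = normalize_nps(radial_power_spectrum(
                movie, n_bins=int(cfg.get("n_bins", 256))))
            entry = {
                "nps_suppression_percent": 100 * nps_suppression(spectrum),
                "nps_coincidence_loss_percent":
                    100 * nps_coincidence_loss(spectrum),
            }
            try:
                x_in = float(label)
                if model is not None:
                    entry["model_coincidence_loss_percent"] = \
                        100.0 * coincidence_loss(model, x_in)
            except ValueError:
                pass
            out["rates"][label] = entry
            nps_curves[label] = pd.DataFrame(
                {"freq_physical_nyquist": spectrum.freq,
                 "nnps": spectrum.power})
        return out

    run_stage("nps", nps_stage, cfg is not None)

    # ---- beam off ----------------------------------------------------
    cfg = config.get("beam_off")

    def beam_off_stage():
        movie = _load_or_none(cfg)
        if movie is None:
            movie = simulate_beam_off(
                spec, tuple(cfg.get("shape", (1024, 1024))),
                float(cfg.get("duration", 10.0)), seed=seeds["beam_off"])
        return {"false_positive_rate": false_positive_rate_estimate(movie)}

    run_stage("beam_off", beam_off_stage, cfg is not None)

    # ---- MTF ---------------------------------------------------------
    cfg = config.get("edge")
    mtf_curve = None

    def mtf_stage():
        nonlocal mtf_curve
        movie = _load_or_none(cfg)
        if movie is None:
            movie = simulate_edge_movie(
                spec, float(cfg.get("angle", 5.0)),
                float(cfg.get("offset", 0.0)),
                float(cfg.get("input_eps", 12.0)),
                float(cfg.get("duration", 30.0)), seed=seeds["mtf"],
                shape=tuple(cfg.get("shape", (256, 192))), accumulate=True)
        edge = fit_edge(movie, roi=cfg.get("roi"))
        mtf_curve = edge_to_mtf(movie, edge,
                                oversample=int(cfg.get("oversample", 8)))
        return {
            "edge_angle_deg": edge.angle,
            "edge_rms_residual_px": edge.rms_line_residual,
            "mtf_at_half_nyquist": mtf_curve.at(0.5),
            "mtf_at_nyquist": mtf_curve.at(1.0),
        }

    run_stage("mtf", mtf_stage, cfg is not None)

    # ---- DQE(0) ------------------------------------------------------
    cfg = config.get("dqe0")
    dqe0_res = None

    def dqe0_stage():
        nonlocal dqe0_res
        movie = _load_or_none(cfg)
        incident = cfg.get("incident_per_pixel")
        if movie is None:
            shape = tuple(cfg.get("shape", (512, 512)))
            duration = float(cfg.get("duration", 2.0))
            x = float(cfg.get("input_eps", 12.5))
            movie, _ = simulate_flat_movie(
                spec, Scene.uniform(shape, x), duration,
                seed=seeds["dqe0"], accumulate=True, ground_truth=False)
            incident = x * duration
        elif incident is None and model is not None:
            x = invert_detected(model, intensity_to_detected_eps(movie))
            incident = x * movie.exposure_time
        dqe0_res = dqe0_noise_binning(movie, incident_per_pixel=incident)
        return {"dqe0": dqe0_res.value, "mode": dqe0_res.mode,
                "v_infinity": dqe0_res.v_infinity,
                "bin_factors": list(dqe0_res.bin_factors),
                "v_curve": list(dqe0_res.v_curve)}

    run_stage("dqe0", dqe0_stage, cfg is not None)

    # ---- DQE curve ---------------------------------------------------
    def dqe_stage():
        curves = dqe_curve(dqe0_res, mtf_curve)
        nps_curves["dqe"] = pd.DataFrame(
            {"freq_physical_nyquist": curves.freq, "mtf": curves.mtf,
             "dqe": curves.dqe})
        return {"dqe0": curves.dqe0, "nnps_assumed": curves.nnps_assumed,
                "dqe_at_half_nyquist": curves.at(0.5, "dqe"),
                "dqe_at_nyquist": curves.at(1.0, "dqe")}

    run_stage("dqe_curve", dqe_stage,
              dqe0_res is not None and mtf_curve is not None)

    # ---- ResLog ------------------------------------------------------
    cfg = config.get("reslog")

    def reslog_stage():
        transform = cfg.get("transform", "reciprocal")
        fits = {}
        for label, rows in cfg["tables"].items():
            fits[label] = fit_reslog(rows, transform=transform)
        out = {"transform": transform, "fits": {
            k: {"slope": f.slope, "intercept": f.intercept,
                "r_squared": f.r_squared} for k, f in fits.items()}}
        labels = list(fits)
        if len(labels) > 1:
            ref = fits[labels[0]]
            out["slope_percent_change_vs_" + labels[0]] = {
                k: slope_percent_change(ref, fits[k]) for k in labels[1:]}
        return out

    run_stage("reslog", reslog_stage,
              cfg is not None and "tables" in (cfg or {}))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        for label, df in nps_curves.items():
            df.to_csv(out_dir / f"curve_{label.replace('.', 'p')}.csv",
                      index=False)
    return report
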