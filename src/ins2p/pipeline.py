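"""End-to-end orchestration: simulate/load -> analyze -> aggregate -> report.

``run_pipeline`` executes the stages in order, writes every stage product
under the configured output directory and returns the run report (also
written as ``report.json``).  Identical config + seed give identical
outputs.  Every summary number in the report is recomputed from the stage
tables, not carried through side channels.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .dose_response import (multiplicity_categories, normalized_dose_response,
                            responder_fractions, rm_anova_bonferroni)
from .dosimetry import (FiberSpec, Medium, OpticalPathSpec, StimulusProtocol,
                        dosimetry_report)
from .io import read_cells_csv, read_traces_csv
from .spatial import CentralEllipse, align_fovs, location_fractions
from .synth import simulate_experiment
from .traces import analyze_trace_array, analyze_traces, baseline_stability

logger = logging.getLogger("ins2p")

__all__ = ["run_pipeline", "build_dosimetry_report"]


def build_dosimetry_report(cfg: RunConfig) -> dict:
    d = cfg.dosimetry
    fiber = FiberSpec(d.core_diameter_um, d.numerical_aperture, d.wavelength_nm)
    path = OpticalPathSpec(d.incidence_angle_deg, d.tip_to_surface_um,
                           tuple(Medium(n, t) for n, t in d.media))
    protocol = StimulusProtocol(d.pulse_width_us, d.rep_rate_hz,
                                d.train_duration_ms, tuple(d.energy_densities))
    return dosimetry_report(fiber, path, protocol)


def _write_json(path: Path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(cfg: RunConfig, write_traces: bool = True) -> dict:
    """Run all stages and return the run report dict."""
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    timings: dict[str, float] = {}
    summary: dict = {}

    def _stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    # ---- dosimetry -------------------------------------------------------
    t0 = _stage("dosimetry")
    dose = build_dosimetry_report(cfg)
    _write_json(outdir / "dosimetry.json", dose)
    manifest["dosimetry.json"] = str(outdir / "dosimetry.json")
    summary["dosimetry"] = {
        "footprint_major_um": dose["footprint"]["major_axis_um"],
        "footprint_minor_um": dose["footprint"]["minor_axis_um"],
        "area_cm2": dose["footprint"]["area_cm2"],
        "alpha_per_cm": dose["absorption"]["alpha_per_cm"],
        "penetration_depth_um": dose["absorption"]["penetration_depth_um"],
        "n_pulses": dose["pulse_train"]["n_pulses"],
        "pulse_energies_uj": dose["pulse_energies_uj"],
    }
    timings["dosimetry"] = time.perf_counter() - t0

    # ---- data: simulate or load -----------------------------------------
    t0 = _stage("data")
    ana = cfg.analysis
    sim = None
    cells_map = None
    if cfg.simulation is not None:
        sim = simulate_experiment(cfg.simulation)
        paths = {} if not write_traces else {
            "traces.csv": str(outdir / "traces.csv")}
        if write_traces:
            sim.traces_frame().to_csv(outdir / "traces.csv", index=False)
        sim.cells_frame().to_csv(outdir / "cells.csv", index=False)
        sim.truth_frame().to_csv(outdir / "ground_truth.csv", index=False)
        paths["cells.csv"] = str(outdir / "cells.csv")
        paths["ground_truth.csv"] = str(outdir / "ground_truth.csv")
        manifest.update(paths)
        cells_map = sim.cells_frame()
    else:
        traces_df = read_traces_csv(cfg.input_traces)
        if cfg.input_cells:
            cells_map = read_cells_csv(cfg.input_cells)
            if "experiment_id" not in cells_map.columns:
                cells_map.insert(0, "experiment_id", "run")
    timings["data"] = time.perf_counter() - t0

    # ---- trace analysis --------------------------------------------------
    t0 = _stage("analyze")
    if sim is not None:
        calls = analyze_trace_array(
            sim.traces, sim.energies, roi_ids=sim.cells["roi_id"].to_numpy(),
            frame_rate=sim.config.frame_rate, stim_onset=sim.config.stim_onset,
            baseline_window=ana.baseline_window,
            response_seconds=ana.response_seconds,
            threshold_k=ana.threshold_k, sigma_mode=ana.sigma_mode)
        calls.insert(0, "experiment_id", sim.experiment_id)
    else:
        calls = analyze_traces(traces_df, frame_rate=ana.frame_rate,
                               stim_onset=ana.stim_onset,
                               baseline_window=ana.baseline_window,
                               response_seconds=ana.response_seconds,
                               threshold_k=ana.threshold_k,
                               sigma_mode=ana.sigma_mode)
        calls.insert(0, "experiment_id", "run")
    calls.to_csv(outdir / "calls.csv", index=False)
    manifest["calls.csv"] = str(outdir / "calls.csv")
    timings["analyze"] = time.perf_counter() - t0

    # ---- dose-response ---------------------------------------------------
    t0 = _stage("dose_response")
    per_exp, fractions = responder_fractions(calls)
    fractions.to_csv(outdir / "responder_fractions.csv", index=False)
    manifest["responder_fractions.csv"] = str(outdir / "responder_fractions.csv")
    summary["responder_fractions_pct"] = {
        f"{row.energy_density:g}": row.mean_pct
        for row in fractions.itertuples()}

    mult = multiplicity_categories(calls)
    mult.per_energy.to_csv(outdir / "multiplicity.csv", index=False)
    manifest["multiplicity.csv"] = str(outdir / "multiplicity.csv")
    summary["multiplicity_counts"] = mult.category_counts

    energies = sorted(calls["energy_density"].unique())
    stats_payload: dict = {}
    curve = None
    if len(energies) >= 2:
        required = tuple(energies[1:])
        try:
            curve = normalized_dose_response(calls, required_energies=required,
                                             reference_energy=energies[-1],
                                             remove_outliers=True)
            curve.to_csv(outdir / "dose_response.csv", index=False)
            manifest["dose_response.csv"] = str(outdir / "dose_response.csv")
            summary["normalized_dose_response_pct"] = {
                f"{row.energy_density:g}": row.normalized_pct
                for row in curve.itertuples()}
        except ValueError as err:
            logger.warning("dose-response curve skipped: %s", err)
        # RM-ANOVA over the highly responsive subset (cells as subjects)
        key = ["experiment_id", "roi_id"]
        peaks = calls.pivot_table(index=key, columns="energy_density",
                                  values="peak_dff")
        resp = calls.pivot_table(index=key, columns="energy_density",
                                 values="is_responder", aggfunc="first")
        keep = resp[list(required)].fillna(False).astype(bool).all(axis=1)
        matrix = peaks.loc[keep].dropna()
        if len(matrix) >= 2:
            omnibus, posthoc = rm_anova_bonferroni(matrix)
            stats_payload["rm_anova"] = omnibus.as_dict()
            stats_payload["posthoc_bonferroni"] = [p.as_dict() for p in posthoc]
    _write_json(outdir / "stats.json", stats_payload)
    manifest["stats.json"] = str(outdir / "stats.json")
    timings["dose_response"] = time.perf_counter() - t0

    # ---- spatial mapping -------------------------------------------------
    t0 = _stage("spatial")
    if cells_map is not None:
        n_resp = (calls.groupby(["experiment_id", "roi_id"])["is_responder"]
                  .sum().rename("multiplicity").reset_index())
        cell_map = cells_map.merge(n_resp, on=["experiment_id", "roi_id"],
                                   how="left").fillna({"multiplicity": 0})
        try:
            overlay = align_fovs(cell_map)
            overlay.cells.to_csv(outdir / "overlay.csv", index=False)
            manifest["overlay.csv"] = str(outdir / "overlay.csv")
            fits = {f"{label}_{axis}": dataclasses.asdict(fit)
                    for (label, axis), fit in overlay.axis_fits.items()}
            _write_json(outdir / "spatial_fits.json", fits)
            manifest["spatial_fits.json"] = str(outdir / "spatial_fits.json")
            summary["spatial_fwhm_um"] = {
                name: fit["fwhm"] for name, fit in fits.items()}
            ellipse = CentralEllipse(center_um=(0.0, 0.0))
            loc = location_fractions(overlay.cells, ellipse)
            _write_json(outdir / "location_fractions.json", loc)
            manifest["location_fractions.json"] = str(
                outdir / "location_fractions.json")
            summary["location_fractions"] = loc
        except ValueError as err:
            logger.warning("spatial stage skipped: %s", err)
    timings["spatial"] = time.perf_counter() - t0

    # ---- baseline stability ---------------------------------------------
    t0 = _stage("baseline")
    if sim is not None:
        from .traces import frame_window
        b0, b1 = frame_window(*ana.baseline_window, sim.config.frame_rate)
        f0s = sim.traces[..., b0:b1].mean(axis=-1)   # (cells, energies, trials)
        recordings = [f0s[:, e, t]
                      for e in range(f0s.shape[1])
                      for t in range(f0s.shape[2])]
        energies_per_rec = [e for e in sim.energies
                            for _ in range(f0s.shape[2])]
        base = baseline_stability(recordings, energies_per_rec)
        base.to_csv(outdir / "baseline_stability.csv", index=False)
        manifest["baseline_stability.csv"] = str(outdir / "baseline_stability.csv")
        summary["baseline_final_over_first"] = float(
            base["f0_normalized"].iloc[-1])
    timings["baseline"] = time.perf_counter() - t0

    for name, dt in timings.items():
        logger.info("stage %s finished in %.2f s", name, dt)
    # timings are logged, not reported: identical config + seed must give
    # byte-identical report files
    report = {
        "version": __version__,
        "config": _config_echo(cfg),
        "manifest": manifest,
        "summary": summary,
    }
    _write_json(outdir / "report.json", report)
    return report


def _config_echo(cfg: RunConfig) -> dict:
    echo = dataclasses.asdict(cfg)
    return echo
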