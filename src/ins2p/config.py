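"""Run configuration: YAML parsing, validation, defaults.

A run config is a YAML document with optional sections; every omitted key
takes the documented default (an empty document is a fully defaulted run).
Validation is eager and aggregates every problem into a single
:class:`ConfigError` rather than failing at the first one.

Sections::

    seed: 0
    output_dir: runs/out
    simulation: {n_cells: 250, noise_sd: 0.01, ...}   # SyntheticConfig keys
    inputs: {traces: path.csv, cells: cells.csv}      # instead of simulation
    analysis: {stim_onset: 5.0, baseline_window: [3.0, 4.5],
               response_seconds: 2.0, threshold_k: 3.0,
               frame_rate: 30.9375, sigma_mode: pooled}
    dosimetry: {core_diameter_um: 105, numerical_aperture: 0.15,
                wavelength_nm: 1470, incidence_angle_deg: 35,
                tip_to_surface_um: 150, media: [[1.34, 0], [1.51, 100],
                [1.36, 0]], energy_densities: [0.35, 0.47, 0.58, 0.70]}
    log_level: INFO
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synth import SyntheticConfig

__all__ = ["ConfigError", "AnalysisParams", "DosimetryParams", "RunConfig",
           "validate_config", "load_config"]


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass(frozen=True)
class AnalysisParams:
    frame_rate: float = 30.9375
    stim_onset: float = 5.0
    baseline_window: tuple[float, float] = (3.0, 4.5)
    response_seconds: float = 2.0
    threshold_k: float = 3.0
    sigma_mode: str = "pooled"


@dataclass(frozen=True)
class DosimetryParams:
    core_diameter_um: float = 105.0
    numerical_aperture: float = 0.15
    wavelength_nm: float = 1470.0
    incidence_angle_deg: float = 35.0
    tip_to_surface_um: float = 150.0
    media: tuple[tuple[float, float], ...] = ((1.34, 0.0), (1.51, 100.0),
                                              (1.36, 0.0))
    pulse_width_us: float = 250.0
    rep_rate_hz: float = 200.0
    train_duration_ms: float = 500.0
    energy_densities: tuple[float, ...] = (0.35, 0.47, 0.58, 0.70)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    output_dir: str = "ins2p_run"
    simulation: SyntheticConfig | None = None
    input_traces: str | None = None
    input_cells: str | None = None
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    dosimetry: DosimetryParams = field(default_factory=DosimetryParams)
    log_level: str = "INFO"


def _check_fields(section: str, raw: dict, cls, errors: list[str]) -> dict:
    """Keep known dataclass fields, record unknown keys as errors."""
    known = {f.name for f in dataclasses.fields(cls)}
    out = {}
    for key, value in raw.items():
        if key not in known:
            errors.append(f"{section}: unknown key {key!r}")
        else:
            out[key] = value
    return out


def _tupleize(value):
    if isinstance(value, list):
        return tuple(_tupleize(v) for v in value)
    return value


def validate_config(raw: dict | str | None) -> RunConfig:
    """Parse and range-check a raw config (YAML text or mapping).

    Returns a fully materialized :class:`RunConfig`; raises
    :class:`ConfigError` listing every problem found.
    """
    if isinstance(raw, str):
        raw = yaml.safe_load(raw)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["config document must be a mapping"])
    errors: list[str] = []
    known_top = {"seed", "output_dir", "simulation", "inputs", "analysis",
                 "dosimetry", "log_level"}
    for key in raw:
        if key not in known_top:
            errors.append(f"unknown top-level key {key!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed must be an integer")
        seed = 0

    sim = None
    if "simulation" in raw and raw["simulation"] is not None:
        sim_raw = {k: _tupleize(v)
                   for k, v in _check_fields("simulation", raw["simulation"],
                                             SyntheticConfig, errors).items()}
        sim_raw.setdefault("seed", seed)
        try:
            sim = SyntheticConfig(**sim_raw)
        except (TypeError, ValueError) as err:
            errors.append(f"simulation: {err}")

    input_traces = input_cells = None
    inputs = raw.get("inputs") or {}
    if inputs:
        for key in set(inputs) - {"traces", "cells"}:
            errors.append(f"inputs: unknown key {key!r}")
        input_traces = inputs.get("traces")
        input_cells = inputs.get("cells")
        for label, path in [("traces", input_traces), ("cells", input_cells)]:
            if path is not None and not Path(path).exists():
                errors.append(f"inputs.{label}: path does not exist: {path}")
    if sim is not None and input_traces is not None:
        errors.append("give either a simulation section or input traces, not both")
    if sim is None and input_traces is None:
        sim = SyntheticConfig(seed=seed)   # fully defaulted simulated run

    ana_raw = {k: _tupleize(v)
               for k, v in _check_fields("analysis", raw.get("analysis") or {},
                                         AnalysisParams, errors).items()}
    analysis = AnalysisParams()
    try:
        analysis = AnalysisParams(**ana_raw)
    except TypeError as err:
        errors.append(f"analysis: {err}")
    if analysis.threshold_k <= 0:
        errors.append("analysis.threshold_k must be > 0")
    if analysis.frame_rate <= 0:
        errors.append("analysis.frame_rate must be > 0")
    if analysis.sigma_mode not in ("pooled", "averaged"):
        errors.append("analysis.sigma_mode must be 'pooled' or 'averaged'")
    bw = analysis.baseline_window
    if not (len(bw) == 2 and bw[0] < bw[1]):
        errors.append("analysis.baseline_window must be (start, end) with start < end")
    elif bw[1] > analysis.stim_onset:
        errors.append("analysis.baseline_window must end at or before the "
                      "stimulus onset")
    if analysis.response_seconds <= 0:
        errors.append("analysis.response_seconds must be > 0")

    dos_raw = {k: _tupleize(v)
               for k, v in _check_fields("dosimetry", raw.get("dosimetry") or {},
                                         DosimetryParams, errors).items()}
    dosimetry = DosimetryParams()
    try:
        dosimetry = DosimetryParams(**dos_raw)
    except TypeError as err:
        errors.append(f"dosimetry: {err}")
    if dosimetry.core_diameter_um <= 0:
        errors.append("dosimetry.core_diameter_um must be > 0")
    if not 0 < dosimetry.numerical_aperture < 1:
        errors.append("dosimetry.numerical_aperture must be in (0, 1)")
    if not 0 < dosimetry.incidence_angle_deg <= 90:
        errors.append("dosimetry.incidence_angle_deg must be in (0, 90]")
    if any(e <= 0 for e in dosimetry.energy_densities):
        errors.append("dosimetry.energy_densities must be > 0")

    log_level = str(raw.get("log_level", "INFO")).upper()
    if log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
        errors.append(f"log_level not recognized: {log_level}")

    if errors:
        raise ConfigError(errors)
    return RunConfig(seed=seed, output_dir=str(raw.get("output_dir", "ins2p_run")),
                     simulation=sim, input_traces=input_traces,
                     input_cells=input_cells, analysis=analysis,
                     dosimetry=dosimetry, log_level=log_level)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(fh.read())
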