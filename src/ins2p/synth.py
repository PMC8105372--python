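"""Synthetic INS experiments with known ground truth.

The generator emulates the study design end to end: cells scattered
uniformly in a field of view at Layer-2/3 depths, a Gaussian elliptical
fluence footprint attenuated in depth by Beer-Lambert water absorption,
per-cell activation thresholds drawn from a log-normal distribution
(photothermal threshold model: a cell responds at an energy density iff the
local fluence reaches its threshold, which makes responder sets nested
across energies by construction), saturating response amplitudes,
GCaMP6f-like double-exponential transients, additive noise and optional
slow bleaching across recordings.  Every quantity the analysis pipeline is
supposed to recover is stored as ground truth.

Defaults: 4 energy densities (0.35/0.47/0.58/0.70 J cm^-2) x 5 trials,
30 s recordings at 30.9375 Hz with the stimulus at 5 s, 250 cells in a
300 x 300 um FoV under a 246 x 168 um footprint.  The threshold
distribution (log-normal, median 0.17 J cm^-2, sigma 0.5) is a calibrated
modelling choice, not independent evidence: it reproduces the qualitative
recruitment ladder (monotone, saturating) and the central-vs-peripheral
recruitment patterns, within the reach of a pure Gaussian-beam threshold
model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosimetry import (BeamFootprint, FluenceField, build_fluence_field,
                        interpolate_absorption, load_water_table,
                        pulse_energy)

__all__ = [
    "SyntheticConfig",
    "SimulationResult",
    "kernel_peak_time",
    "transient_kernel",
    "sample_cells",
    "make_fluence_fields",
    "recruit",
    "synthesize_traces",
    "simulate_experiment",
    "simulate_study",
    "render_movie",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of one synthetic experiment."""

    seed: int = 0
    n_cells: int = 250
    fov_um: tuple[float, float] = (300.0, 300.0)
    footprint_major_um: float = 246.0
    footprint_minor_um: float = 168.0
    beam_offset_um: tuple[float, float] = (0.0, 0.0)
    energy_densities: tuple[float, ...] = (0.35, 0.47, 0.58, 0.70)
    threshold_median: float = 0.17    # J cm^-2, log-normal median
    threshold_sigma: float = 0.5      # log-normal sigma (ln units)
    amplitude_max: float = 0.30       # saturating peak dF/F0
    amplitude_scale: float = 0.15     # J cm^-2, saturation scale
    tau_rise: float = 0.08            # s
    tau_decay: float = 0.4            # s
    noise_sd: float = 0.01            # dF/F0 units (times F0)
    noise_model: str = "gaussian"     # or "poisson"
    bleach_rate: float = 0.0          # per recording, exponential on F0
    trials_per_energy: int = 5
    frame_rate: float = 30.9375       # Hz
    duration: float = 30.0            # s
    stim_onset: float = 5.0           # s
    depth_range_um: tuple[float, float] = (96.0, 255.0)
    f0_range: tuple[float, float] = (500.0, 1500.0)
    wavelength_nm: float = 1470.0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be > 0")
        if self.fov_um[0] <= 0 or self.fov_um[1] <= 0:
            raise ValueError("FoV must have positive extent")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("kinetic time constants must be > 0")
        if self.threshold_median <= 0 or self.threshold_sigma < 0:
            raise ValueError("invalid threshold distribution")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("rates and durations must be > 0")
        if self.stim_onset >= self.duration:
            raise ValueError("stimulus onset must precede the end")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        if self.trials_per_energy < 1:
            raise ValueError("need at least one trial per energy")

    @property
    def n_frames(self) -> int:
        return int(self.duration * self.frame_rate)

    @property
    def beam_center_um(self) -> tuple[float, float]:
        return (self.fov_um[0] / 2.0 + self.beam_offset_um[0],
                self.fov_um[1] / 2.0 + self.beam_offset_um[1])

    def footprint(self) -> BeamFootprint:
        return BeamFootprint(major_axis_um=self.footprint_major_um,
                             minor_axis_um=self.footprint_minor_um,
                             center_um=self.beam_center_um)


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time after onset at which the double-exponential transient peaks."""
    return tau_rise * np.log((tau_rise + tau_decay) / tau_rise)


def transient_kernel(t: np.ndarray, onset: float, tau_rise: float,
                     tau_decay: float) -> np.ndarray:
    """Unit-peak double-exponential calcium transient.

    g(t) = (1 - exp(-(t-onset)/tau_rise)) * exp(-(t-onset)/tau_decay) for
    t > onset, zero before, scaled so its continuous-time maximum is 1
    (the amplitude passed to the generator is therefore the true peak
    dF/F0, up to frame sampling).
    """
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("time constants must be > 0")
    d = np.asarray(t, dtype=float) - onset
    g = np.where(d > 0,
                 (1.0 - np.exp(-np.clip(d, 0, None) / tau_rise))
                 * np.exp(-np.clip(d, 0, None) / tau_decay), 0.0)
    r = tau_rise / (tau_rise + tau_decay)
    gmax = (1.0 - r) * ((tau_rise + tau_decay) / tau_rise) ** (-tau_rise / tau_decay)
    return g / gmax


def sample_cells(config: SyntheticConfig,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Uniform cell positions and depths with i.i.d. log-normal thresholds."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    return pd.DataFrame({
        "roi_id": np.arange(1, n + 1),
        "x_um": rng.uniform(0.0, config.fov_um[0], n),
        "y_um": rng.uniform(0.0, config.fov_um[1], n),
        "depth_um": rng.uniform(*config.depth_range_um, n),
        "threshold_j_cm2": np.exp(rng.normal(np.log(config.threshold_median),
                                             config.threshold_sigma, n)),
        "f0": rng.uniform(*config.f0_range, n),
    })


def make_fluence_fields(config: SyntheticConfig) -> dict[float, FluenceField]:
    """One fluence field per energy density, built from the dosimetry model."""
    footprint = config.footprint()
    alpha = interpolate_absorption(load_water_table(), config.wavelength_nm)
    area = footprint.area_cm2
    return {e: build_fluence_field(footprint, pulse_energy(e, area), alpha)
            for e in config.energy_densities}


def recruit(cells: pd.DataFrame,
            fields: dict[float, FluenceField],
            amplitude_max: float = 0.30,
            amplitude_scale: float = 0.15) -> pd.DataFrame:
    """Ground-truth responder flags and peak amplitudes.

    A cell responds at energy e iff the local fluence at its position and
    depth reaches its threshold; its true peak amplitude then follows the
    saturating law A_max * (1 - exp(-(fluence - threshold) / scale)).
    """
    rows = []
    x = cells["x_um"].to_numpy()
    y = cells["y_um"].to_numpy()
    z = cells["depth_um"].to_numpy()
    theta = cells["threshold_j_cm2"].to_numpy()
    for e in sorted(fields):
        f = np.asarray(fields[e].fluence(x, y, z))
        responds = f >= theta
        amplitude = np.where(
            responds,
            amplitude_max * (1.0 - np.exp(-np.clip(f - theta, 0, None)
                                          / amplitude_scale)),
            0.0)
        rows.append(pd.DataFrame({
            "roi_id": cells["roi_id"],
            "energy_density": e,
            "fluence_j_cm2": f,
            "responds": responds,
            "amplitude": amplitude,
        }))
    return pd.concat(rows, ignore_index=True)


def synthesize_traces(cells: pd.DataFrame, truth: pd.DataFrame,
                      config: SyntheticConfig,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Raw fluorescence movies as an array (n_cells, n_energies, n_trials,
    n_frames).

    F(t) = F0 * bleach_r * (1 + A * g(t)) + noise, with g the unit-peak
    transient kernel, bleach_r = exp(-bleach_rate * recording_index)
    (recordings ordered energy-major, trials within energy) and Gaussian
    noise of SD noise_sd * F0 (or Poisson counts of the clean trace).
    The five trials of an energy share A and differ only in noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    energies = sorted(config.energy_densities)
    n_cells = len(cells)
    n_e, n_tr, n_fr = len(energies), config.trials_per_energy, config.n_frames
    t = np.arange(n_fr) / config.frame_rate
    g = transient_kernel(t, config.stim_onset, config.tau_rise,
                         config.tau_decay)

    amp = (truth.pivot(index="roi_id", columns="energy_density",
                       values="amplitude")
           .loc[cells["roi_id"], energies].to_numpy())       # (cells, energies)
    f0 = cells["f0"].to_numpy()[:, None, None, None]
    clean = 1.0 + amp[:, :, None, None] * g[None, None, None, :]
    rec_idx = (np.arange(n_e) * n_tr)[:, None] + np.arange(n_tr)[None, :]
    bleach = np.exp(-config.bleach_rate * rec_idx)[None, :, :, None]
    clean = f0 * bleach * clean
    if config.noise_model == "gaussian":
        noise = rng.normal(0.0, 1.0, size=(n_cells, n_e, n_tr, n_fr))
        out = clean + config.noise_sd * f0 * noise
    else:
        out = rng.poisson(clean).astype(float)
    return out


@dataclass
class SimulationResult:
    """One synthetic experiment: configuration, truth and raw traces."""

    config: SyntheticConfig
    cells: pd.DataFrame
    truth: pd.DataFrame
    traces: np.ndarray  # (n_cells, n_energies, n_trials, n_frames)
    experiment_id: str = "sim"

    @property
    def energies(self) -> list[float]:
        return sorted(self.config.energy_densities)

    def traces_frame(self) -> pd.DataFrame:
        """Long-format trace table (the on-disk CSV schema)."""
        n_c, n_e, n_tr, n_fr = self.traces.shape
        roi = self.cells["roi_id"].to_numpy()
        idx = pd.MultiIndex.from_product(
            [roi, self.energies, np.arange(1, n_tr + 1), np.arange(n_fr)],
            names=["roi_id", "energy_density_J_cm2", "trial", "frame"])
        frame = pd.DataFrame({"F": self.traces.reshape(-1)}, index=idx)
        return frame.reset_index()[
            ["roi_id", "trial", "energy_density_J_cm2", "frame", "F"]]

    def cells_frame(self) -> pd.DataFrame:
        out = self.cells.copy()
        out.insert(0, "experiment_id", self.experiment_id)
        return out

    def truth_frame(self) -> pd.DataFrame:
        out = self.truth.copy()
        out.insert(0, "experiment_id", self.experiment_id)
        return out

    def ground_truth_fractions(self) -> pd.DataFrame:
        """True responder fraction (%) per energy density."""
        return (self.truth.groupby("energy_density")["responds"]
                .mean().mul(100.0).rename("fraction_pct").reset_index())

    def write(self, outdir) -> dict[str, str]:
        """Write traces.csv, cells.csv, ground_truth.csv and a config echo."""
        import pathlib

        import yaml

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in [("traces.csv", self.traces_frame()),
                            ("cells.csv", self.cells_frame()),
                            ("ground_truth.csv", self.truth_frame())]:
            path = outdir / name
            frame.to_csv(path, index=False)
            paths[name] = str(path)
        cfg_path = outdir / "config.yaml"
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self.config), fh,
                           default_flow_style=False)
        paths["config.yaml"] = str(cfg_path)
        return paths


def simulate_experiment(config: SyntheticConfig,
                        experiment_id: str = "sim") -> SimulationResult:
    """Run the full generator: cells, recruitment truth, raw traces."""
    rng = np.random.default_rng(config.seed)
    cells = sample_cells(config, rng)
    fields = make_fluence_fields(config)
    truth = recruit(cells, fields, config.amplitude_max,
                    config.amplitude_scale)
    traces = synthesize_traces(cells, truth, config, rng)
    return SimulationResult(config=config, cells=cells, truth=truth,
                            traces=traces, experiment_id=experiment_id)


def simulate_study(config: SyntheticConfig,
                   beam_offsets: list[tuple[float, float]]
                   ) -> dict[str, SimulationResult]:
    """Several experiments differing in fiber placement (beam offset).

    Experiment ``exp{i}`` uses ``beam_offsets[i]`` and an independent seed
    derived from the base seed, mirroring repeated sessions in which the
    fiber lands at slightly different positions in the field of view.
    """
    results = {}
    for i, offset in enumerate(beam_offsets):
        cfg = dataclasses.replace(config, seed=config.seed + 1000 * (i + 1),
                                  beam_offset_um=tuple(offset))
        exp_id = f"exp{i + 1}"
        results[exp_id] = simulate_experiment(cfg, experiment_id=exp_id)
    return results


def render_movie(cells: pd.DataFrame, traces: np.ndarray,
                 config: SyntheticConfig, px_size_um: float = 4.0,
                 blob_sigma_um: float = 5.0, mask_radius_um: float = 8.0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Render cells as Gaussian blobs into a movie plus a label mask.

    ``traces`` is (n_cells, n_frames) of raw F for one recording.  Each
    cell's blob is scaled so that the mean over its own mask pixels equals
    its F value, so mean-over-mask extraction inverts the rendering exactly
    up to 16-bit quantization (and blob overlap, if cells are close).
    Returns (movie uint16 (T, H, W), mask uint16 (H, W)).
    """
    n_cells, n_frames = np.asarray(traces).shape
    if n_cells != len(cells):
        raise ValueError("traces row count must match cells")
    w = int(np.ceil(config.fov_um[0] / px_size_um))
    h = int(np.ceil(config.fov_um[1] / px_size_um))
    sigma_px = blob_sigma_um / px_size_um
    if min(h, w) < 4 or sigma_px < 0.5:
        raise ValueError("pixel grid too small to render blobs")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=np.uint16)
    weights = np.zeros((n_cells, h, w))
    for i, row in enumerate(cells.itertuples()):
        cx = row.x_um / px_size_um
        cy = row.y_um / px_size_um
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        blob = np.exp(-r2 / (2.0 * sigma_px ** 2))
        in_mask = r2 <= (mask_radius_um / px_size_um) ** 2
        if not in_mask.any():
            raise ValueError(f"cell {row.roi_id} falls outside the pixel grid")
        mask[in_mask] = row.roi_id
        weights[i] = blob / blob[in_mask].mean()
    movie = np.einsum("ct,chw->thw", np.asarray(traces, dtype=float), weights)
    vmax = np.iinfo(np.uint16).max
    if movie.max() > vmax:
        import warnings
        warnings.warn("rendered intensities exceed uint16 range; clamping",
                      stacklevel=2)
    return np.clip(movie, 0, vmax).astype(np.uint16), mask
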