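"""Raw fluorescence to dF/F0, responder classification, baseline stability.

The normalized signal is dF/F0 = (F - F0)/F0, with F0 the mean raw
fluorescence over a fixed pre-stimulus baseline window (3.0-4.5 s for a
stimulus at 5 s).  A cell is called a responder at a given energy density
when the peak of its trial-averaged dF/F0 in the response window exceeds
``threshold_k`` times the baseline noise sigma_F (SNR = peak / sigma_F > k,
strict inequality, k = 3 by default).

Two conventions for sigma_F are provided:

``"pooled"`` (default)
    sigma_F is the pooled standard deviation of the *single-trial* dF/F0
    baselines.  The detection threshold then scales with the single-trial
    noise while the peak is read from the n-trial average, so the criterion
    tightens as sqrt(n) with trial averaging and its false-positive rate on
    pure noise is negligible.
``"averaged"``
    sigma_F is the baseline standard deviation of the trial-averaged trace
    itself.  This reading is scale-free: on pure noise the max over a ~2 s
    response window exceeds 3 sigma for roughly one cell in ten regardless
    of the noise level, so it is kept only as an alternative reading.

Frame/time mapping: the frame holding time t is floor(t * frame_rate);
windows (start, end) are half-open, frames [floor(start*rate),
floor(end*rate)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecording",
    "DffTrace",
    "ResponseCall",
    "frame_window",
    "compute_f0",
    "compute_dff",
    "trial_average",
    "classify_response",
    "analyze_roi",
    "analyze_traces",
    "baseline_stability",
    "tukey_outliers",
]

DEFAULT_FRAME_RATE = 30.9375      # Hz, resonant-scanning preset
DEFAULT_BASELINE = (3.0, 4.5)     # s, pre-stimulus window
DEFAULT_STIM_ONSET = 5.0          # s
DEFAULT_RESPONSE_SECONDS = 2.0    # s after onset


class DegenerateBaselineError(ValueError):
    """Baseline mean is non-positive or the window holds too few frames."""


@dataclass
class TrialRecording:
    """One ROI's raw fluorescence for a single stimulation trial."""

    roi_id: int | str
    trial: int
    energy_density: float
    frames: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    stim_onset: float = DEFAULT_STIM_ONSET

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 1:
            raise ValueError("frames must be a 1-D array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("fluorescence values must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def duration(self) -> float:
        return self.frames.size / self.frame_rate


@dataclass
class DffTrace:
    """Normalized dF/F0 trace with its baseline statistics."""

    roi_id: int | str
    energy_density: float
    dff: np.ndarray
    f0: float
    sigma_baseline: float
    frame_rate: float = DEFAULT_FRAME_RATE
    n_trials_averaged: int = 1
    degenerate_sd: bool = False


@dataclass
class ResponseCall:
    """Per-cell, per-energy responder decision."""

    roi_id: int | str
    energy_density: float
    peak_dff: float
    snr: float
    is_responder: bool
    threshold_k: float = 3.0
    response_window: tuple[float, float] = field(
        default=(DEFAULT_STIM_ONSET, DEFAULT_STIM_ONSET + DEFAULT_RESPONSE_SECONDS))


def frame_window(start_s: float, end_s: float, frame_rate: float) -> tuple[int, int]:
    """Half-open frame-index interval [floor(start*rate), floor(end*rate))."""
    if end_s <= start_s:
        raise ValueError("window end must exceed start")
    return (int(np.floor(start_s * frame_rate)),
            int(np.floor(end_s * frame_rate)))


def compute_f0(recording: TrialRecording,
               window: tuple[float, float] = DEFAULT_BASELINE) -> float:
    """Baseline mean fluorescence over the pre-stimulus window."""
    if window[1] > recording.stim_onset:
        raise ValueError("baseline window must precede the stimulus onset")
    i0, i1 = frame_window(window[0], window[1], recording.frame_rate)
    if i1 > recording.frames.size:
        raise ValueError("baseline window extends past the recording")
    if i1 - i0 < 2:
        raise DegenerateBaselineError("baseline window holds fewer than 2 frames")
    f0 = float(recording.frames[i0:i1].mean())
    if f0 <= 0:
        raise DegenerateBaselineError("baseline mean must be > 0")
    return f0


def compute_dff(recording: TrialRecording, f0: float | None = None,
                baseline_window: tuple[float, float] = DEFAULT_BASELINE) -> DffTrace:
    """dF/F0 trace; sigma_baseline is the sample SD of dF/F0 in the window."""
    if f0 is None:
        f0 = compute_f0(recording, baseline_window)
    if f0 <= 0:
        raise DegenerateBaselineError("f0 must be > 0")
    dff = (recording.frames - f0) / f0
    i0, i1 = frame_window(*baseline_window, recording.frame_rate)
    sigma = float(dff[i0:i1].std(ddof=1))
    return DffTrace(roi_id=recording.roi_id,
                    energy_density=recording.energy_density,
                    dff=dff, f0=f0, sigma_baseline=sigma,
                    frame_rate=recording.frame_rate)


def trial_average(traces: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, bool]:
    """Pointwise mean and sample SD across trials.

    Unequal lengths are truncated to the shortest with a warning.  For a
    single trace the SD is reported as zeros with ``degenerate=True``.
    Returns ``(mean, sd, degenerate)``.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    arrays = [np.asarray(t, dtype=float) for t in traces]
    n = min(a.size for a in arrays)
    if any(a.size != n for a in arrays):
        warnings.warn("traces of unequal length; truncating to shortest",
                      stacklevel=2)
        arrays = [a[:n] for a in arrays]
    stack = np.vstack(arrays)
    mean = stack.mean(axis=0)
    if stack.shape[0] == 1:
        return mean, np.zeros(n), True
    return mean, stack.std(axis=0, ddof=1), False


def classify_response(mean_trace: DffTrace,
                      response_window: tuple[float, float] | None = None,
                      threshold_k: float = 3.0,
                      stim_onset: float = DEFAULT_STIM_ONSET) -> ResponseCall:
    """3-sigma responder criterion on a (usually trial-averaged) dF/F0 trace.

    ``peak_dff`` is the maximum of the trace in the response window (no
    smoothing); the cell is a responder iff ``peak / sigma_baseline``
    strictly exceeds ``threshold_k``.
    """
    if response_window is None:
        response_window = (stim_onset, stim_onset + DEFAULT_RESPONSE_SECONDS)
    if mean_trace.sigma_baseline <= 0:
        raise DegenerateBaselineError(
            "sigma_baseline is zero; SNR undefined for this trace")
    i0, i1 = frame_window(*response_window, mean_trace.frame_rate)
    if i1 > mean_trace.dff.size or i0 < 0:
        raise ValueError("response window extends past the trace")
    peak = float(mean_trace.dff[i0:i1].max())
    snr = peak / mean_trace.sigma_baseline
    return ResponseCall(roi_id=mean_trace.roi_id,
                        energy_density=mean_trace.energy_density,
                        peak_dff=peak, snr=snr,
                        is_responder=bool(snr > threshold_k),
                        threshold_k=threshold_k,
                        response_window=response_window)


def analyze_roi(recordings: list[TrialRecording],
                baseline_window: tuple[float, float] = DEFAULT_BASELINE,
                response_window: tuple[float, float] | None = None,
                threshold_k: float = 3.0,
                sigma_mode: str = "pooled") -> tuple[ResponseCall, DffTrace]:
    """Average one ROI's trials at one energy and classify the response.

    Each trial is normalized with its own baseline, the dF/F0 traces are
    averaged pointwise, and sigma_F is taken either as the pooled
    single-trial baseline SD (default) or from the averaged trace's
    baseline (``sigma_mode="averaged"``).
    """
    if sigma_mode not in ("pooled", "averaged"):
        raise ValueError("sigma_mode must be 'pooled' or 'averaged'")
    if len(recordings) == 0:
        raise ValueError("need at least one recording")
    per_trial = [compute_dff(r, baseline_window=baseline_window)
                 for r in recordings]
    mean, _, degenerate = trial_average([t.dff for t in per_trial])
    rate = per_trial[0].frame_rate
    i0, i1 = frame_window(*baseline_window, rate)
    if sigma_mode == "pooled":
        sigma = float(np.sqrt(np.mean([t.sigma_baseline ** 2 for t in per_trial])))
    else:
        sigma = float(mean[i0:i1].std(ddof=1))
    avg = DffTrace(roi_id=per_trial[0].roi_id,
                   energy_density=per_trial[0].energy_density,
                   dff=mean,
                   f0=float(np.mean([t.f0 for t in per_trial])),
                   sigma_baseline=sigma, frame_rate=rate,
                   n_trials_averaged=len(per_trial),
                   degenerate_sd=degenerate)
    stim_onset = recordings[0].stim_onset
    call = classify_response(avg, response_window, threshold_k,
                             stim_onset=stim_onset)
    return call, avg


def analyze_traces(frame: pd.DataFrame,
                   frame_rate: float = DEFAULT_FRAME_RATE,
                   stim_onset: float = DEFAULT_STIM_ONSET,
                   baseline_window: tuple[float, float] = DEFAULT_BASELINE,
                   response_seconds: float = DEFAULT_RESPONSE_SECONDS,
                   threshold_k: float = 3.0,
                   sigma_mode: str = "pooled") -> pd.DataFrame:
    """Classify every (ROI, energy) group of a long-format trace table.

    ``frame`` columns: roi_id, trial, energy_density_J_cm2, frame, F
    (the on-disk CSV schema).  Returns one row per ROI x energy with
    f0, sigma_baseline, peak_dff, snr, is_responder and n_trials.
    """
    required = {"roi_id", "trial", "energy_density_J_cm2", "frame", "F"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"trace table lacks columns: {sorted(missing)}")
    response_window = (stim_onset, stim_onset + response_seconds)
    rows = []
    for (roi, energy), group in frame.groupby(["roi_id", "energy_density_J_cm2"],
                                              sort=True):
        recs = []
        for trial, tgroup in group.groupby("trial", sort=True):
            f = tgroup.sort_values("frame")["F"].to_numpy()
            recs.append(TrialRecording(roi_id=roi, trial=int(trial),
                                       energy_density=float(energy), frames=f,
                                       frame_rate=frame_rate,
                                       stim_onset=stim_onset))
        call, avg = analyze_roi(recs, baseline_window, response_window,
                                threshold_k, sigma_mode)
        rows.append({"roi_id": roi, "energy_density": float(energy),
                     "f0": avg.f0, "sigma_baseline": avg.sigma_baseline,
                     "peak_dff": call.peak_dff, "snr": call.snr,
                     "is_responder": call.is_responder,
                     "n_trials": avg.n_trials_averaged})
    return pd.DataFrame(rows)


def analyze_trace_array(F: np.ndarray, energies, roi_ids=None,
                        frame_rate: float = DEFAULT_FRAME_RATE,
                        stim_onset: float = DEFAULT_STIM_ONSET,
                        baseline_window: tuple[float, float] = DEFAULT_BASELINE,
                        response_seconds: float = DEFAULT_RESPONSE_SECONDS,
                        threshold_k: float = 3.0,
                        sigma_mode: str = "pooled") -> pd.DataFrame:
    """Vectorized equivalent of :func:`analyze_traces` for an in-memory array.

    ``F`` has shape (n_cells, n_energies, n_trials, n_frames); ``energies``
    matches axis 1.  Identical numbers to the long-format path, without the
    per-group Python loop.
    """
    if sigma_mode not in ("pooled", "averaged"):
        raise ValueError("sigma_mode must be 'pooled' or 'averaged'")
    F = np.asarray(F, dtype=float)
    if F.ndim != 4:
        raise ValueError("F must be (n_cells, n_energies, n_trials, n_frames)")
    n_cells, n_e, n_tr, n_fr = F.shape
    if len(energies) != n_e:
        raise ValueError("energies must match F's second axis")
    b0, b1 = frame_window(*baseline_window, frame_rate)
    r0, r1 = frame_window(stim_onset, stim_onset + response_seconds, frame_rate)
    if r1 > n_fr or b1 > n_fr:
        raise ValueError("analysis windows extend past the traces")
    f0 = F[..., b0:b1].mean(axis=-1, keepdims=True)
    if np.any(f0 <= 0):
        raise DegenerateBaselineError("non-positive baseline mean encountered")
    dff = F / f0 - 1.0
    mean_dff = dff.mean(axis=2)
    if sigma_mode == "pooled":
        sigma = np.sqrt(
            (dff[..., b0:b1].std(axis=-1, ddof=1) ** 2).mean(axis=2))
    else:
        sigma = mean_dff[..., b0:b1].std(axis=-1, ddof=1)
    if np.any(sigma <= 0):
        raise DegenerateBaselineError("zero baseline SD encountered")
    peak = mean_dff[..., r0:r1].max(axis=-1)
    snr = peak / sigma
    if roi_ids is None:
        roi_ids = np.arange(1, n_cells + 1)
    roi_col = np.repeat(np.asarray(roi_ids), n_e)
    energy_col = np.tile(np.asarray(list(energies), dtype=float), n_cells)
    return pd.DataFrame({
        "roi_id": roi_col,
        "energy_density": energy_col,
        "f0": f0[..., 0].mean(axis=2).reshape(-1),
        "sigma_baseline": sigma.reshape(-1),
        "peak_dff": peak.reshape(-1),
        "snr": snr.reshape(-1),
        "is_responder": (snr > threshold_k).reshape(-1),
        "n_trials": n_tr,
    })


def baseline_stability(f0_per_recording: list[np.ndarray],
                       energy_densities: list[float] | None = None) -> pd.DataFrame:
    """Baseline F0 time course across successive recordings.

    ``f0_per_recording`` holds, per recording in temporal order, the array
    of per-ROI baseline means.  Each recording's mean F0 across ROIs is
    normalized to the first recording's value (so the first entry is exactly
    1) and the SEM across ROIs is propagated on the same scale.
    """
    if len(f0_per_recording) == 0:
        raise ValueError("need at least one recording")
    ref = float(np.mean(f0_per_recording[0]))
    if ref <= 0:
        raise ValueError("first recording's baseline must be > 0")
    rows = []
    for idx, f0s in enumerate(f0_per_recording):
        f0s = np.asarray(f0s, dtype=float)
        mean = float(f0s.mean())
        sem = float(f0s.std(ddof=1) / np.sqrt(f0s.size)) if f0s.size > 1 else 0.0
        rows.append({
            "recording_index": idx,
            "energy_density": (energy_densities[idx]
                               if energy_densities is not None else np.nan),
            "f0_normalized": 1.0 if idx == 0 else mean / ref,
            "sem": sem / ref,
        })
    return pd.DataFrame(rows)


def _tukey_hinges(sorted_values: np.ndarray) -> tuple[float, float]:
    """Lower/upper Tukey hinges: medians of the lower and upper halves, the
    overall median included in both halves when n is odd."""
    n = sorted_values.size
    half = (n + 1) // 2
    return (float(np.median(sorted_values[:half])),
            float(np.median(sorted_values[n - half:])))


def tukey_outliers(values) -> tuple[np.ndarray, np.ndarray]:
    """Boxplot-rule outliers: outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles are Tukey hinges (documented convention).  With fewer than 4
    values the rule is a no-op with a warning.  Returns (kept, flags).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("fewer than 4 values; outlier rule skipped", stacklevel=2)
        return values, np.zeros(values.size, dtype=bool)
    q1, q3 = _tukey_hinges(np.sort(values))
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flags = (values < lo) | (values > hi)
    return values[~flags], flags
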