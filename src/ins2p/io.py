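"""File formats: long-format trace CSVs, calls tables, TIFF movies/masks.

On-disk schemas
---------------
traces.csv
    roi_id, trial, energy_density_J_cm2, frame, F — one row per frame of
    one trial of one ROI.
cells.csv
    experiment_id, roi_id, x_um, y_um, depth_um (extra columns pass through).
calls.csv
    roi_id, energy_density, f0, sigma_baseline, peak_dff, snr,
    is_responder, n_trials (+ experiment_id when present).
Movies are multi-page TIFFs; ROI masks are label images (pixel value =
roi_id, 0 = background).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

TRACE_COLUMNS = ["roi_id", "trial", "energy_density_J_cm2", "frame", "F"]


def read_traces_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def write_traces_csv(frame: pd.DataFrame, path) -> None:
    frame[TRACE_COLUMNS].to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"roi_id", "x_um", "y_um"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def write_movie(path, movie: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(movie))


def read_movie(path) -> np.ndarray:
    return tifffile.imread(path)


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path)


def extract_roi_traces(movie: np.ndarray, mask: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Mean fluorescence over each labelled ROI, per frame.

    ``movie`` is (T, H, W), ``mask`` a label image (0 = background).
    Returns (roi_ids, traces) with traces of shape (n_rois, T).
    """
    movie = np.asarray(movie, dtype=float)
    mask = np.asarray(mask)
    if movie.ndim != 3 or mask.shape != movie.shape[1:]:
        raise ValueError("movie must be (T, H, W) with a matching mask")
    roi_ids = np.unique(mask)
    roi_ids = roi_ids[roi_ids != 0]
    flat = movie.reshape(movie.shape[0], -1)
    traces = np.empty((roi_ids.size, movie.shape[0]))
    for i, roi in enumerate(roi_ids):
        sel = (mask == roi).reshape(-1)
        traces[i] = flat[:, sel].mean(axis=1)
    return roi_ids, traces


def movie_to_trace_frame(movie: np.ndarray, mask: np.ndarray, trial: int,
                         energy_density: float) -> pd.DataFrame:
    """Extraction straight into the long-format trace schema."""
    roi_ids, traces = extract_roi_traces(movie, mask)
    n_rois, n_frames = traces.shape
    return pd.DataFrame({
        "roi_id": np.repeat(roi_ids, n_frames),
        "trial": trial,
        "energy_density_J_cm2": energy_density,
        "frame": np.tile(np.arange(n_frames), n_rois),
        "F": traces.reshape(-1),
    })
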