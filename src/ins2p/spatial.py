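"""Spatial extent of recruitment across fields of view.

Different imaging sessions place the fiber footprint at slightly different
positions in the field of view.  To pool them, each experiment's cell map
is shifted so that the spatial distribution maximum of its multiple
(3x + 4x) responders sits at the origin -- for a normal distribution the
fitted mean *is* the mode, so the shift is simply minus the per-axis mean
of the 3x + 4x cells (a kernel-density mode is available as an
alternative).  Per-axis normal fits then summarize each multiplicity class
by mu, sigma and FWHM = 2 sqrt(2 ln 2) sigma, and cells are classified as
central or peripheral by membership in the exposure ellipse (246 x 168 um
by default, boundary counts as inside).

Coordinates are micrometres in the image convention: origin at the FoV
top-left, x rightward, y downward.  Depth is carried but the membership
test is planar.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FWHM_FACTOR",
    "AxisFit",
    "CentralEllipse",
    "AlignedOverlay",
    "fit_axis_normal",
    "align_fovs",
    "ellipse_membership",
    "location_fractions",
    "multiplicity_class",
]

#: FWHM of a normal distribution in units of sigma.
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

CLASS_LABELS = ("1x", "2x", "3x+4x")


def multiplicity_class(n_responsive) -> pd.Series:
    """Map a per-cell count of responsive energies (0..4) to its class label
    ('0', '1x', '2x', '3x+4x')."""
    n = pd.Series(n_responsive)
    return pd.cut(n, bins=[-0.5, 0.5, 1.5, 2.5, 4.5],
                  labels=("0",) + CLASS_LABELS).astype(str)


@dataclass(frozen=True)
class AxisFit:
    mu: float
    sigma: float
    fwhm: float
    n: int
    degenerate: bool = False


def fit_axis_normal(coordinates) -> AxisFit:
    """Normal fit along one axis: sample mean/SD and the implied FWHM."""
    x = np.asarray(coordinates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 coordinates")
    mu = float(x.mean())
    sigma = float(x.std(ddof=1))
    if sigma == 0.0:
        return AxisFit(mu=mu, sigma=0.0, fwhm=0.0, n=x.size, degenerate=True)
    return AxisFit(mu=mu, sigma=sigma, fwhm=FWHM_FACTOR * sigma, n=x.size)


def _kde_mode(x: np.ndarray) -> float:
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


@dataclass(frozen=True)
class CentralEllipse:
    """The central-beam region: exposure-footprint-sized ellipse."""

    center_um: tuple[float, float] = (0.0, 0.0)
    major_axis_um: float = 246.0
    minor_axis_um: float = 168.0
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.major_axis_um >= self.minor_axis_um > 0:
            raise ValueError("require major >= minor > 0")


@dataclass
class AlignedOverlay:
    """Pooled, per-experiment-shifted cell coordinates with per-axis fits."""

    shifts: dict  # experiment_id -> (dx, dy) um
    cells: pd.DataFrame  # x_um, y_um shifted; multiplicity class column
    axis_fits: dict  # (class label, 'x'|'y') -> AxisFit
    excluded_experiments: list = field(default_factory=list)


def align_fovs(cell_map: pd.DataFrame, min_cells: int = 2,
               center_mode: str = "mean") -> AlignedOverlay:
    """Center every experiment on its multiple-responder distribution maximum.

    ``cell_map`` columns: experiment_id, roi_id, x_um, y_um and
    multiplicity (class label or responsive-energy count).  Per experiment
    the shift is minus the per-axis center of the 3x + 4x cells (mean by
    default, ``center_mode="kde"`` for the kernel-density mode); all cells
    are shifted, no rotation is applied.  Experiments with fewer than
    ``min_cells`` multiple responders are excluded with a warning.
    """
    required = {"experiment_id", "roi_id", "x_um", "y_um", "multiplicity"}
    missing = required - set(cell_map.columns)
    if missing:
        raise ValueError(f"cell map lacks columns: {sorted(missing)}")
    if center_mode not in ("mean", "kde"):
        raise ValueError("center_mode must be 'mean' or 'kde'")
    cells = cell_map.copy()
    if np.issubdtype(cells["multiplicity"].dtype, np.number):
        cells["multiplicity"] = multiplicity_class(cells["multiplicity"]).values

    shifts: dict = {}
    excluded: list = []
    shifted = []
    for exp_id, group in cells.groupby("experiment_id", sort=True):
        multi = group[group["multiplicity"] == "3x+4x"]
        if len(multi) < min_cells:
            warnings.warn(f"experiment {exp_id!r} has fewer than {min_cells} "
                          "multiple responders; excluded from the overlay",
                          stacklevel=2)
            excluded.append(exp_id)
            continue
        if center_mode == "mean":
            cx = float(multi["x_um"].mean())
            cy = float(multi["y_um"].mean())
        else:
            cx = _kde_mode(multi["x_um"].to_numpy())
            cy = _kde_mode(multi["y_um"].to_numpy())
        shifts[exp_id] = (-cx, -cy)
        g = group.copy()
        g["x_um"] = g["x_um"] - cx
        g["y_um"] = g["y_um"] - cy
        shifted.append(g)
    if not shifted:
        raise ValueError("no experiment has enough multiple responders")
    pooled = pd.concat(shifted, ignore_index=True)

    axis_fits = {}
    for label in CLASS_LABELS:
        sub = pooled[pooled["multiplicity"] == label]
        for axis in ("x", "y"):
            if len(sub) >= 2:
                axis_fits[(label, axis)] = fit_axis_normal(
                    sub[f"{axis}_um"].to_numpy())
    return AlignedOverlay(shifts=shifts, cells=pooled, axis_fits=axis_fits,
                          excluded_experiments=excluded)


def ellipse_membership(x_um, y_um, ellipse: CentralEllipse) -> np.ndarray:
    """Boolean mask: point inside (or on) the ellipse.

    Inside iff (x'/a)^2 + (y'/b)^2 <= 1 with a, b the semi-axes and
    (x', y') the point in the ellipse-aligned frame.
    """
    x = np.asarray(x_um, dtype=float) - ellipse.center_um[0]
    y = np.asarray(y_um, dtype=float) - ellipse.center_um[1]
    theta = math.radians(ellipse.orientation_deg)
    xr = x * math.cos(theta) + y * math.sin(theta)
    yr = -x * math.sin(theta) + y * math.cos(theta)
    a = ellipse.major_axis_um / 2.0
    b = ellipse.minor_axis_um / 2.0
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def location_fractions(cells: pd.DataFrame,
                       ellipse: CentralEllipse | None = None) -> dict:
    """Central vs peripheral responsiveness and per-class central shares.

    ``cells`` columns: x_um, y_um, multiplicity (label or count; '0' =
    never responsive).  Reports the percentage of central (inside-ellipse)
    cells responding to at least one energy, the same for peripheral cells,
    and for each multiplicity class the percentage of its cells lying
    inside.  An empty region yields None for its percentage.
    """
    if ellipse is None:
        ellipse = CentralEllipse()
    cells = cells.copy()
    if np.issubdtype(cells["multiplicity"].dtype, np.number):
        cells["multiplicity"] = multiplicity_class(cells["multiplicity"]).values
    inside = ellipse_membership(cells["x_um"].to_numpy(),
                                cells["y_um"].to_numpy(), ellipse)
    responsive = (cells["multiplicity"] != "0").to_numpy()

    def _pct(mask):
        return float(100.0 * responsive[mask].mean()) if mask.any() else None

    central_shares = {}
    for label in CLASS_LABELS:
        sel = (cells["multiplicity"] == label).to_numpy()
        central_shares[label] = (float(100.0 * inside[sel].mean())
                                 if sel.any() else None)
    return {
        "central_responsive_pct": _pct(inside),
        "peripheral_responsive_pct": _pct(~inside),
        "n_central": int(inside.sum()),
        "n_peripheral": int((~inside).sum()),
        "central_share_by_class_pct": central_shares,
    }
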