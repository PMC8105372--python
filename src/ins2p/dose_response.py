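"""Population dose-response aggregation and statistics.

Takes per-cell, per-energy responder calls (the output of
:mod:`ins2p.traces`) and produces the population-level results: the fraction
of responding cells per energy density, the multiplicity breakdown (how many
distinct energy densities each cell responds to), the amplitude
dose-response normalized to the highest energy, and the accompanying
two-sample t-tests and one-way repeated-measures ANOVA with Bonferroni
post-hoc comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .traces import tukey_outliers

__all__ = [
    "StatResult",
    "MultiplicityTable",
    "responder_fractions",
    "multiplicity_categories",
    "normalized_dose_response",
    "two_sample_t",
    "rm_anova_bonferroni",
]

MULTIPLICITY_LABELS = ("1x", "2x", "3x+4x")


@dataclass
class StatResult:
    method: str
    statistic: float
    df: tuple[float, ...] | float
    p_value: float
    comparison: str = ""

    def as_dict(self) -> dict:
        return {"method": self.method, "statistic": self.statistic,
                "df": self.df, "p_value": self.p_value,
                "comparison": self.comparison}


@dataclass
class MultiplicityTable:
    """Partition of responders by how many energies they respond to.

    ``category_counts`` maps '1x'/'2x'/'3x+4x' to cell counts (cells
    responding to exactly one, exactly two, or three-or-four energies).
    ``per_energy`` holds, for each energy, its total responder count and the
    decomposition of those responders by overall multiplicity class.
    ``per_cell`` maps cell id to its set of responsive energies.
    """

    category_counts: dict[str, int]
    per_energy: pd.DataFrame
    per_cell: dict = field(repr=False, default_factory=dict)

    @property
    def n_responders(self) -> int:
        return sum(self.category_counts.values())


def _require_columns(calls: pd.DataFrame, columns: set[str]) -> None:
    missing = columns - set(calls.columns)
    if missing:
        raise ValueError(f"calls table lacks columns: {sorted(missing)}")


def responder_fractions(calls: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of responding cells per energy density.

    ``calls`` needs columns experiment_id, roi_id, energy_density,
    is_responder.  Returns ``(per_experiment, summary)``: per-experiment
    percentages, and the unweighted cross-experiment mean with SEM (each
    experiment counts as one observation).
    """
    _require_columns(calls, {"experiment_id", "roi_id", "energy_density",
                             "is_responder"})
    if calls.empty:
        raise ValueError("empty calls table")
    grouped = calls.groupby(["experiment_id", "energy_density"])
    per_exp = grouped["is_responder"].agg(
        n_total="size", n_responders="sum").reset_index()
    if (per_exp["n_total"] == 0).any():
        raise ValueError("experiment with no cells at some energy")
    per_exp["fraction_pct"] = 100.0 * per_exp["n_responders"] / per_exp["n_total"]

    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    summary = per_exp.groupby("energy_density")["fraction_pct"].agg(
        mean_pct="mean", sem_pct=_sem, n_experiments="size").reset_index()
    return per_exp, summary


def multiplicity_categories(calls: pd.DataFrame,
                            energies: list[float] | None = None
                            ) -> MultiplicityTable:
    """Categorize responders by the number of energies they respond to.

    Every cell must have a call at every energy; cells with missing
    evaluations are excluded with a warning.  The three categories (exactly
    one, exactly two, three-or-four energies) partition the responder set;
    each energy's responders are additionally decomposed by the responding
    cell's overall class.
    """
    _require_columns(calls, {"roi_id", "energy_density", "is_responder"})
    energies = sorted(energies if energies is not None
                      else calls["energy_density"].unique())
    key = ["roi_id"]
    if "experiment_id" in calls.columns:
        key = ["experiment_id", "roi_id"]
    pivot = calls.pivot_table(index=key, columns="energy_density",
                              values="is_responder", aggfunc="first")
    complete = pivot.reindex(columns=energies).notna().all(axis=1)
    if (~complete).any():
        warnings.warn(f"{int((~complete).sum())} cells lack calls at some "
                      "energy; excluded from multiplicity", stacklevel=2)
    pivot = pivot.loc[complete, energies].astype(bool)

    n_responsive = pivot.sum(axis=1)
    labels = pd.cut(n_responsive, bins=[0.5, 1.5, 2.5, 4.5],
                    labels=MULTIPLICITY_LABELS)
    category_counts = {lab: int((labels == lab).sum())
                       for lab in MULTIPLICITY_LABELS}

    rows = []
    for e in energies:
        resp = pivot[e]
        row = {"energy_density": e, "n_responders": int(resp.sum())}
        for lab in MULTIPLICITY_LABELS:
            row[lab] = int((resp & (labels == lab)).sum())
        rows.append(row)
    per_cell = {idx: set(np.array(energies)[row.to_numpy()])
                for idx, row in pivot.iterrows()}
    return MultiplicityTable(category_counts=category_counts,
                             per_energy=pd.DataFrame(rows),
                             per_cell=per_cell)


def normalized_dose_response(calls: pd.DataFrame,
                             required_energies=(0.47, 0.58, 0.70),
                             reference_energy: float = 0.70,
                             remove_outliers: bool = False
                             ) -> pd.DataFrame:
    """Amplitude dose-response of the highly responsive population.

    The subset rule keeps cells that respond to *all* ``required_energies``
    (regardless of their behaviour at the lowest dose).  Per energy, the
    mean peak dF/F0 and its SEM over that subset are reported, plus the
    normalized value: 100 x mean(e) / mean(reference).  With
    ``remove_outliers`` the boxplot rule is applied to the peaks per energy
    (per experiment when an experiment_id column is present) before
    aggregation.
    """
    _require_columns(calls, {"roi_id", "energy_density", "is_responder",
                             "peak_dff"})
    key = ["roi_id"]
    if "experiment_id" in calls.columns:
        key = ["experiment_id", "roi_id"]
    resp = calls.pivot_table(index=key, columns="energy_density",
                             values="is_responder", aggfunc="first")
    try:
        keep = resp[list(required_energies)].fillna(False).astype(bool).all(axis=1)
    except KeyError as err:
        raise ValueError(f"required energy missing from calls: {err}") from None
    subset_idx = resp.index[keep]
    if len(subset_idx) == 0:
        raise ValueError("no cell responds to all required energies")

    sel = calls.set_index(key).loc[subset_idx].reset_index()
    if remove_outliers:
        group_cols = ["energy_density"] + (
            ["experiment_id"] if "experiment_id" in calls.columns else [])
        kept = []
        for _, g in sel.groupby(group_cols):
            if len(g) >= 4:
                _, flags = tukey_outliers(g["peak_dff"].to_numpy())
                g = g.loc[~flags]
            kept.append(g)
        sel = pd.concat(kept, ignore_index=True)

    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    curve = sel.groupby("energy_density")["peak_dff"].agg(
        mean_peak="mean", sem=_sem, n_cells="size").reset_index()
    ref_rows = curve.loc[curve["energy_density"] == reference_energy]
    if ref_rows.empty:
        raise ValueError("reference energy absent from calls")
    ref_mean = float(ref_rows["mean_peak"].iloc[0])
    if ref_mean <= 0:
        raise ValueError("reference mean must be > 0")
    curve["normalized_pct"] = 100.0 * curve["mean_peak"] / ref_mean
    return curve


def two_sample_t(a, b, welch: bool = False) -> StatResult:
    """Two-sided two-sample t-test (pooled variance by default).

    Degenerate zero-variance input: equal means give t = 0, p = 1; unequal
    means give an infinite t with p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    method = "Welch t-test" if welch else "two-sample t-test (pooled)"
    df = (a.size + b.size - 2) if not welch else np.nan
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return StatResult(method, 0.0, df, 1.0)
        sign = np.sign(a.mean() - b.mean())
        return StatResult(method, float(sign * np.inf), df, 0.0,
                          comparison="zero pooled variance, unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        # Welch-Satterthwaite df
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return StatResult(method, float(t), float(df), float(p))


def rm_anova_bonferroni(matrix: pd.DataFrame,
                        pairs: str = "adjacent"
                        ) -> tuple[StatResult, list[StatResult]]:
    """One-way repeated-measures ANOVA plus Bonferroni paired comparisons.

    ``matrix`` is subjects x conditions (columns ordered by condition, e.g.
    energy density), complete (no imputation).  The omnibus within-subjects
    F has df (k-1, (k-1)(n-1)).  Post-hoc paired t-tests cover adjacent
    condition pairs by default (or every pair with ``pairs="all"``); each p
    is multiplied by the number of performed comparisons and capped at 1.
    """
    data = matrix.to_numpy(dtype=float)
    if np.isnan(data).any():
        raise ValueError("incomplete subjects-by-conditions matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")

    # within-subject decomposition; identical conditions give F = 0, p = 1
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if ss_cond <= 1e-300:
        omnibus = StatResult("one-way RM ANOVA", 0.0, (df1, df2), 1.0)
    elif ss_err <= 1e-300:
        omnibus = StatResult("one-way RM ANOVA", float(np.inf), (df1, df2), 0.0,
                             comparison="zero error variance")
    else:
        f = (ss_cond / df1) / (ss_err / df2)
        p = float(stats.f.sf(f, df1, df2))
        omnibus = StatResult("one-way RM ANOVA", float(f), (df1, df2), p)

    cols = list(matrix.columns)
    if pairs == "adjacent":
        pair_idx = [(i, i + 1) for i in range(k - 1)]
    elif pairs == "all":
        pair_idx = [(i, j) for i in range(k) for j in range(i + 1, k)]
    else:
        raise ValueError("pairs must be 'adjacent' or 'all'")
    m = len(pair_idx)
    posthoc = []
    for i, j in pair_idx:
        d = data[:, j] - data[:, i]
        if np.allclose(d.std(ddof=1), 0.0):
            t, p = (0.0, 1.0) if np.allclose(d.mean(), 0.0) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_rel(data[:, i], data[:, j])
        posthoc.append(StatResult(
            "paired t, Bonferroni", float(t), n - 1,
            float(min(1.0, p * m)),
            comparison=f"{cols[i]} vs {cols[j]}"))
    return omnibus, posthoc
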