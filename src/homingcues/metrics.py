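"""Performance metrics: accuracy/precision summaries, clutter-effect
deltas, bootstrap confidence intervals, participant classification, and
exclusion filtering.

Accuracy is the median position error of a participant within a condition;
precision is the standard deviation of position error (lower SD = higher
precision).  Clutter effects are per-participant differences on the raw vm
scale: the low-clutter delta compares zero vs. three objects and the
high-clutter delta three vs. 99 objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import Point2D, position_errors
from .synthetic import TRIAL_COLUMNS

__all__ = [
    "exclusion_filter",
    "summarize_performance",
    "clutter_deltas",
    "bootstrap_median_ci",
    "classify_participants",
    "ci_outlier_group",
    "accuracy_precision_correlation",
    "delta_density",
    "normality_check",
]

_GOAL = Point2D(0.0, 0.0)


def _require_schema(trials: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing column(s): {', '.join(missing)}")


def exclusion_filter(raw_trials: pd.DataFrame, max_sessions: int = 4,
                     drop_incomplete_participants: bool = False
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study's exclusion rules to a raw trial table.

    Removes invalid trials (missing endpoints), drops sessions beyond
    ``max_sessions`` (keeping the dataset balanced), and optionally drops
    participants missing any condition entirely.  Returns the clean table
    and a report of counts per rule.
    """
    _require_schema(raw_trials)
    report = {"input_trials": len(raw_trials)}

    valid = raw_trials["valid"].astype(bool) & raw_trials[["x", "y"]].notna().all(axis=1)
    report["invalid_trials_removed"] = int((~valid).sum())
    clean = raw_trials[valid]

    in_sessions = clean["session"] <= max_sessions
    report["late_session_trials_removed"] = int((~in_sessions).sum())
    clean = clean[in_sessions]

    report["participants_removed"] = 0
    if drop_incomplete_participants and len(clean):
        n_conditions = clean["condition"].nunique()
        counts = clean.groupby("participant")["condition"].nunique()
        complete = counts[counts == n_conditions].index
        report["participants_removed"] = int(clean["participant"].nunique() - len(complete))
        clean = clean[clean["participant"].isin(complete)]

    report["output_trials"] = len(clean)
    return clean.reset_index(drop=True), report


def summarize_performance(trials: pd.DataFrame, goal: Point2D = _GOAL) -> pd.DataFrame:
    """Per participant x condition accuracy (median position error) and
    precision (SD of position error, n-1 denominator).

    Cells without valid trials are omitted with a warning; the SD of a
    single-trial cell is reported as NaN.
    """
    _require_schema(trials)
    valid = trials[trials["valid"].astype(bool)].copy()
    n_cells_in = trials.groupby(["participant", "condition"]).ngroups
    if valid.empty:
        warnings.warn("no valid trials to summarize", stacklevel=2)
        return pd.DataFrame(columns=["participant", "condition", "median_error",
                                     "sd_error", "n_trials"])
    valid["error"] = position_errors(valid[["x", "y"]].to_numpy(float), goal)
    summary = (valid.groupby(["participant", "condition"])["error"]
               .agg(median_error="median",
                    sd_error=lambda e: e.std(ddof=1),
                    n_trials="size")
               .reset_index())
    if len(summary) < n_cells_in:
        warnings.warn(f"omitted {n_cells_in - len(summary)} empty participant/condition "
                      "cell(s)", stacklevel=2)
    return summary


def clutter_deltas(summary: pd.DataFrame, low: tuple[int, int] = (0, 3),
                   high: tuple[int, int] = (3, 99)) -> pd.DataFrame:
    """Per-participant clutter-effect differences on the raw vm scale.

    ``delta_low_*`` is condition ``low[0]`` minus ``low[1]`` (positive =
    improvement as the first objects are added); ``delta_high_*`` is
    ``high[0]`` minus ``high[1]`` (negative = impairment in dense clutter),
    for both the median (accuracy) and the SD (precision).  Participants
    missing any required condition are skipped with a warning.
    """
    needed = sorted({*low, *high})
    wide_med = summary.pivot(index="participant", columns="condition", values="median_error")
    wide_sd = summary.pivot(index="participant", columns="condition", values="sd_error")
    for cond in needed:
        if cond not in wide_med.columns:
            wide_med[cond] = np.nan
            wide_sd[cond] = np.nan
    complete = wide_med[needed].notna().all(axis=1)
    if not complete.all():
        warnings.warn(f"skipped {int((~complete).sum())} participant(s) missing "
                      f"condition(s) among {needed}", stacklevel=2)
    wide_med, wide_sd = wide_med[complete], wide_sd[complete]
    return pd.DataFrame({
        "participant": wide_med.index,
        "delta_low_median": (wide_med[low[0]] - wide_med[low[1]]).to_numpy(),
        "delta_low_sd": (wide_sd[low[0]] - wide_sd[low[1]]).to_numpy(),
        "delta_high_median": (wide_med[high[0]] - wide_med[high[1]]).to_numpy(),
        "delta_high_sd": (wide_sd[high[0]] - wide_sd[high[1]]).to_numpy(),
    }).reset_index(drop=True)


def bootstrap_median_ci(values, B: int = 1000, conf: float = 0.95,
                        seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the median.

    Constant input yields a zero-width interval (not an error).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if B < 100:
        raise ValueError("B must be >= 100")
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, values.size))
    medians = np.median(values[idx], axis=1)
    lo, hi = np.percentile(medians, [100.0 * (1 - conf) / 2.0, 100.0 * (1 + conf) / 2.0])
    return float(lo), float(hi)


def _trial_errors(trials: pd.DataFrame, goal: Point2D) -> pd.DataFrame:
    valid = trials[trials["valid"].astype(bool)].copy()
    valid["error"] = position_errors(valid[["x", "y"]].to_numpy(float), goal)
    return valid


def classify_participants(trials: pd.DataFrame, cond_a: int = 3, cond_b: int = 99,
                          alpha: float = 0.05, goal: Point2D = _GOAL) -> pd.DataFrame:
    """Classify each participant's performance change from ``cond_a`` to
    ``cond_b`` with a two-sample Wilcoxon rank-sum test on single-trial
    position errors.

    Labels: ``worse`` / ``better`` when the test is significant at
    ``alpha`` (direction by the median difference), ``unchanged``
    otherwise, ``indeterminate`` with fewer than two trials in either
    condition.  The exact null distribution is used for small samples
    without ties, the tie-corrected normal approximation otherwise.
    """
    _require_schema(trials)
    errors = _trial_errors(trials, goal)
    rows = []
    for participant, group in errors.groupby("participant"):
        a = group.loc[group["condition"] == cond_a, "error"].to_numpy()
        b = group.loc[group["condition"] == cond_b, "error"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append((participant, np.nan, np.nan, np.nan, np.nan, "indeterminate"))
            continue
        method = "exact" if (max(len(a), len(b)) < 20
                             and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
                             ) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        if res.pvalue < alpha:
            label = "worse" if med_b > med_a else "better"
        else:
            label = "unchanged"
        rows.append((participant, float(res.statistic), float(res.pvalue),
                     med_a, med_b, label))
    return pd.DataFrame(rows, columns=["participant", "statistic", "p_value",
                                       f"median_{cond_a}", f"median_{cond_b}", "label"])


def ci_outlier_group(deltas: pd.DataFrame, column: str = "delta_high_median",
                     B: int = 10000, conf: float = 0.95, seed: int = 0) -> pd.DataFrame:
    """Group participants by whether their clutter delta falls outside the
    bootstrapped confidence interval of the cohort's median delta.

    This is the CI-based grouping reported alongside the rank-sum
    classification; the two procedures need not agree and are surfaced side
    by side.
    """
    values = deltas[column].to_numpy(float)
    lo, hi = bootstrap_median_ci(values, B=B, conf=conf, seed=seed)
    group = np.where(values < lo, "declined",
                     np.where(values > hi, "improved", "within_ci"))
    out = deltas[["participant", column]].copy()
    out["ci_low"], out["ci_high"], out["group"] = lo, hi, group
    return out


def accuracy_precision_correlation(summary: pd.DataFrame, condition: int
                                   ) -> tuple[float, float, float]:
    """Pearson correlation between accuracy (median error) and precision
    (SD of error) across participants within one condition.

    Returns ``(r, r_squared, p)``; NaNs with a warning when either measure
    has zero variance.
    """
    cell = summary[summary["condition"] == condition]
    acc = cell["median_error"].to_numpy(float)
    prec = cell["sd_error"].to_numpy(float)
    if len(cell) < 3:
        raise ValueError("need >= 3 participants in the condition")
    if np.std(acc) == 0.0 or np.std(prec) == 0.0:
        warnings.warn("zero variance in accuracy or precision; correlation undefined",
                      stacklevel=2)
        return float("nan"), float("nan"), float("nan")
    r, p = sps.pearsonr(acc, prec)
    return float(r), float(r) ** 2, float(p)


def delta_density(values, grid: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel-density summary (Silverman bandwidth) of a delta
    distribution; a reporting utility only."""
    values = np.asarray(values, dtype=float)
    kde = sps.gaussian_kde(values, bw_method="silverman")
    if grid is None:
        pad = 3.0 * values.std()
        grid = np.linspace(values.min() - pad, values.max() + pad, 256)
    return grid, kde(grid)


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test of a delta distribution: ``(W, p)``."""
    res = sps.shapiro(np.asarray(values, dtype=float))
    return float(res.statistic), float(res.pvalue)
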