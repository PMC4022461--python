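"""Behavioral deviation statistics and group comparisons.

Two per-subject quantities are derived from the behavioral table (reaction
time RT, criterion switch score CS, sensitivity d' — each measured in the
attention [_A] and memory [_M] tasks):

* delta_m: signed deviation of measure m from the cohort mean (both groups
  pooled) — "is this subject an outlier in absolute performance?"
* rel_m: attention-minus-memory difference m_A - m_M — "how unequal are the
  subject's attention and memory performances?"

Group comparisons test whether the secondary state-space groups (pooled)
have larger |delta_m| or |rel_m| than the primary group, with a one-tailed
Welch (unequal-variance) two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MEASURES = ("RT", "CS", "DP")
TASK_COLUMNS = {m: (f"{m}_A", f"{m}_M") for m in MEASURES}
ALL_COLUMNS = [c for pair in TASK_COLUMNS.values() for c in pair]


def behavioral_deviations(
    records: pd.DataFrame,
    measures: tuple[str, ...] = MEASURES,
    normalize_rel: bool = False,
) -> pd.DataFrame:
    """Per-subject signed deviations and attention-vs-memory differences.

    Returns a table with columns ``delta_<col>`` (deviation from the cohort
    mean, per task column) and ``rel_<m>`` (m_A - m_M; optionally normalized
    by the mean magnitude (|m_A|+|m_M|)/2).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 subjects")
    out = pd.DataFrame({"subject_id": records["subject_id"].astype(str)})
    for m in measures:
        col_a, col_m = TASK_COLUMNS[m]
        for col in (col_a, col_m):
            if col not in records.columns:
                raise KeyError(f"behavior table missing column {col}")
            out[f"delta_{col}"] = records[col] - records[col].mean()
        rel = records[col_a] - records[col_m]
        if normalize_rel:
            denom = (records[col_a].abs() + records[col_m].abs()) / 2.0
            rel = rel / denom.replace(0.0, np.nan)
        out[f"rel_{m}"] = rel
    return out


@dataclass(frozen=True)
class GroupTestResult:
    """One-sided Welch t-test of a behavioral magnitude between groups."""

    measure: str
    statistic: float
    df: float
    p_value: float
    mean_secondary: float
    se_secondary: float
    mean_primary: float
    se_primary: float
    alternative: str = "greater"  # secondary exceeds primary


def one_tailed_welch_t(
    values_secondary: np.ndarray,
    values_primary: np.ndarray,
    alternative: str = "greater",
    measure: str = "",
) -> GroupTestResult:
    """Welch two-sample t-test, one-sided.

    ``alternative='greater'`` tests that the secondary-group mean exceeds
    the primary-group mean. Degenerate input (zero variance in both groups
    with equal means) has no defined t statistic and raises.
    """
    x = np.asarray(values_secondary, dtype=float)
    y = np.asarray(values_primary, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        raise ZeroDivisionError("zero variance in both groups with equal means: t undefined")
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return GroupTestResult(
        measure=measure,
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_secondary=float(x.mean()),
        se_secondary=float(stats.sem(x)),
        mean_primary=float(y.mean()),
        se_primary=float(stats.sem(y)),
        alternative=alternative,
    )


def _sem_or_nan(values: np.ndarray) -> float:
    return float(stats.sem(values)) if len(values) >= 2 else float("nan")


def group_behavior_report(
    deviations: pd.DataFrame, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Mean and standard error of |delta_m| and |rel_m| per group and measure.

    ``assignments`` must have columns subject_id and group; the two
    secondary groups are additionally pooled into a ``secondary`` row, the
    unit the group comparisons are run on. Single-subject cells get a
    missing (NaN) standard error with a warning.
    """
    merged = deviations.merge(
        assignments[["subject_id", "group"]], on="subject_id", validate="one_to_one"
    )
    if len(merged) != len(deviations):
        raise ValueError("assignments do not cover all behavioral subjects")
    merged["pooled"] = np.where(merged["group"] == "primary", "primary", "secondary")
    value_cols = [c for c in deviations.columns if c.startswith(("delta_", "rel_"))]
    rows = []
    group_sets = [("group", g) for g in ("primary", "secondary_RM", "secondary_RA")]
    group_sets += [("pooled", "secondary")]
    for key, g in group_sets:
        sub = merged[merged[key] == g]
        if sub.empty:
            warnings.warn(f"group {g} is empty; cells reported missing", stacklevel=2)
        for col in value_cols:
            vals = sub[col].abs().to_numpy()
            if len(vals) == 1:
                warnings.warn(f"group {g}, {col}: single subject, SE missing", stacklevel=2)
            rows.append(
                {
                    "group": g,
                    "measure": col,
                    "n": len(vals),
                    "mean_abs": float(vals.mean()) if len(vals) else float("nan"),
                    "se_abs": _sem_or_nan(vals),
                }
            )
    return pd.DataFrame(rows)


def group_behavior_tests(
    deviations: pd.DataFrame,
    assignments: pd.DataFrame,
    columns: tuple[str, ...] = ("delta_RT_A", "delta_RT_M", "rel_DP", "rel_CS"),
) -> list[GroupTestResult]:
    """One-tailed secondary-vs-primary Welch tests on |delta_m| / |rel_m|."""
    merged = deviations.merge(assignments[["subject_id", "group"]], on="subject_id")
    primary = merged[merged["group"] == "primary"]
    secondary = merged[merged["group"] != "primary"]
    results = []
    for col in columns:
        results.append(
            one_tailed_welch_t(
                secondary[col].abs().to_numpy(),
                primary[col].abs().to_numpy(),
                alternative="greater",
                measure=col,
            )
        )
    return results
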