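"""Cohort descriptives and group comparisons.

Classical between-group tests for the demographic/clinical table:
pooled-variance two-sample t-tests for quantitative variables (the pooled
form is used because the table's degrees of freedom equal
``n_a + n_b - 2``), Pearson chi-squared tests without continuity
correction for sex distributions, and a Kolmogorov-Smirnov normality
check (with sample-estimated parameters, hence approximate) used as a
gate before the t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Cohort, Group

__all__ = [
    "TestResult",
    "GroupSummary",
    "pooled_t_test",
    "pooled_t_test_from_summary",
    "chi_squared_2x2",
    "ks_normality",
    "summarize_variable",
    "cohort_table",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple
    p_value: float
    test_name: str
    degenerate: bool = False


@dataclass(frozen=True)
class GroupSummary:
    variable: str
    group: str
    n: int
    minimum: float
    maximum: float
    mean: float
    sd: float


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    return arr[np.isfinite(arr)]


def pooled_t_test(values_a, values_b) -> TestResult:
    """Classical pooled-variance two-sample t-test (df = n_a + n_b - 2)."""
    a, b = _clean(values_a), _clean(values_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    df = len(a) + len(b) - 2
    pooled_var = (
        (len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)
    ) / df
    if pooled_var <= 0:
        return TestResult(0.0, df, 1.0, "pooled t-test", degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(float(t), df, float(p), "pooled t-test")


def pooled_t_test_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> TestResult:
    """Same statistic computed from per-group summaries (mean, SD, n)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if pooled_var <= 0:
        return TestResult(0.0, df, 1.0, "pooled t-test", degenerate=True)
    t, p = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True
    )
    return TestResult(float(t), df, float(p), "pooled t-test")


def chi_squared_2x2(table) -> TestResult:
    """Pearson chi-squared on a 2x2 table, no continuity correction, df = 1."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("all row and column totals must be positive")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return TestResult(float(chi2), int(df), float(p), "Pearson chi-squared")


def ks_normality(values) -> TestResult:
    """One-sample KS test against a normal with sample-estimated mean/SD.

    Approximate: estimating the parameters from the sample makes the
    asymptotic KS p-value conservative (Lilliefors effect); used here only
    as a screening gate, not an inferential endpoint.
    """
    arr = _clean(values)
    if len(arr) < 5:
        raise ValueError("need at least 5 observations")
    sd = float(np.std(arr, ddof=1))
    if sd == 0:
        return TestResult(0.0, len(arr), 1.0, "Kolmogorov-Smirnov", degenerate=True)
    stat, p = stats.kstest(arr, "norm", args=(float(np.mean(arr)), sd))
    return TestResult(float(stat), len(arr), float(p), "Kolmogorov-Smirnov")


def summarize_variable(variable: str, group: str, values) -> GroupSummary:
    arr = _clean(values)
    if len(arr) == 0:
        return GroupSummary(variable, group, 0, math.nan, math.nan, math.nan, math.nan)
    return GroupSummary(
        variable=variable,
        group=group,
        n=len(arr),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        mean=float(arr.mean()),
        sd=float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0,
    )


_EYE_VARS = ["age", "bcva", "iop", "cupping", "md", "psd"]


def cohort_table(cohort: Cohort) -> pd.DataFrame:
    """Demographic/clinical comparison table for a cohort.

    Rows: eye- and subject-level sex distributions (chi-squared), subject-
    and eye-level age plus the clinical covariates (pooled t-tests, missing
    values dropped per variable).
    """
    recs = cohort.records
    ctrl = [r for r in recs if r.group == Group.CONTROL]
    glau = [r for r in recs if r.group == Group.GLAUCOMA]
    rows = []

    def sex_counts(items):
        male = sum(1 for r in items if r.sex == "male")
        female = sum(1 for r in items if r.sex == "female")
        return male, female

    # eye-level and subject-level sex tables
    for label, c_items, g_items in (
        ("eyes_by_sex", ctrl, glau),
        (
            "patients_by_sex",
            list({r.subject_id: r for r in ctrl}.values()),
            list({r.subject_id: r for r in glau}.values()),
        ),
    ):
        cm, cf = sex_counts(c_items)
        gm, gf = sex_counts(g_items)
        try:
            res = chi_squared_2x2([[cm, gm], [cf, gf]])
            stat, df, p = res.statistic, res.df, res.p_value
        except ValueError:
            stat, df, p = math.nan, math.nan, math.nan
        rows.append(
            {
                "variable": label,
                "control_n": cm + cf,
                "glaucoma_n": gm + gf,
                "control_mean": math.nan,
                "glaucoma_mean": math.nan,
                "control_sd": math.nan,
                "glaucoma_sd": math.nan,
                "test": "Pearson chi-squared",
                "statistic": stat,
                "df": df,
                "p_value": p,
            }
        )

    def t_row(label, c_vals, g_vals):
        c_arr, g_arr = _clean(c_vals), _clean(g_vals)
        if len(c_arr) < 2 or len(g_arr) < 2:
            return
        res = pooled_t_test(c_arr, g_arr)
        rows.append(
            {
                "variable": label,
                "control_n": len(c_arr),
                "glaucoma_n": len(g_arr),
                "control_mean": float(c_arr.mean()),
                "glaucoma_mean": float(g_arr.mean()),
                "control_sd": float(np.std(c_arr, ddof=1)),
                "glaucoma_sd": float(np.std(g_arr, ddof=1)),
                "test": res.test_name,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
        )

    subj_age = {}
    for r in recs:
        subj_age.setdefault(r.subject_id, (r.group, r.age))
    t_row(
        "patients_by_age",
        [a for g, a in subj_age.values() if g == Group.CONTROL],
        [a for g, a in subj_age.values() if g == Group.GLAUCOMA],
    )
    for var in _EYE_VARS:
        label = "eyes_by_age" if var == "age" else var
        t_row(
            label,
            [getattr(r, var) for r in ctrl],
            [getattr(r, var) for r in glau],
        )
    return pd.DataFrame(rows)
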