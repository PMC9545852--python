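"""Hypothesis tests comparing means and variances across sequences,
field strengths, and vendors.

Means are compared with a one-way repeated-measures (within-subject)
ANOVA — each subject contributes one value per condition, and the
condition effect is tested against the subject-by-condition residual:
``F = MS_condition / MS_error`` on ``(k-1, (k-1)(n-1))`` degrees of
freedom.  Significant effects are followed by paired t-tests.
Between-subject measurement variances are compared with Levene's test
(classical mean-centered by default; the median-centered Brown-Forsythe
variant is available).  Raw two-sided p-values are always reported; no
sphericity correction and no multiplicity adjustment are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "DegenerateDataError",
    "ranova_oneway",
    "paired_t",
    "levene",
    "effect_tests",
]


class DegenerateDataError(ValueError):
    """Raised when a test statistic is undefined for the given data."""


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its p-value and degrees of freedom.

    ``df`` is ``(df_num, df_den)`` for F-type tests and a scalar for
    t-type tests.
    """

    statistic: float
    p_value: float
    df: tuple | float
    test_name: str

    __test__ = False  # not a pytest collection target

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def ranova_oneway(values) -> TestResult:
    """One-way within-subject ANOVA on a subjects x conditions table.

    Accepts a 2D array or a wide DataFrame (rows = subjects, columns =
    conditions).  Rows containing NaN are dropped (listwise deletion).
    If the condition effect is exactly zero the result is F = 0, p = 1,
    even when the residual mean square also vanishes.
    """
    if isinstance(values, pd.DataFrame):
        values = values.to_numpy(dtype=float)
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2D subjects x conditions table")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 complete subjects and >= 2 conditions")

    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_cond <= 0:
        f, p = 0.0, 1.0
    elif ms_err <= 0:
        raise DegenerateDataError("zero residual variance with a nonzero effect")
    else:
        f = ms_cond / ms_err
        p = float(stats.f.sf(f, df_cond, df_err))
    return TestResult(statistic=float(f), p_value=p, df=(df_cond, df_err),
                      test_name="ranova_oneway")


def paired_t(values_a, values_b) -> TestResult:
    """Two-sided paired t-test.

    All-zero differences give t = 0, p = 1 exactly; constant nonzero
    differences have an undefined statistic and raise
    :class:`DegenerateDataError`.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired samples must be equal-length 1D with n >= 2")
    diff = a - b
    df = a.size - 1
    if np.all(diff == 0):
        return TestResult(statistic=0.0, p_value=1.0, df=float(df),
                          test_name="paired_t")
    if np.std(diff, ddof=1) == 0:
        raise DegenerateDataError("differences are constant and nonzero")
    res = stats.ttest_rel(a, b)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(df), test_name="paired_t")


def levene(groups, center: str = "mean") -> TestResult:
    """Levene's test of equal variances across groups.

    ``center='mean'`` is the classical test; ``'median'`` gives the
    Brown-Forsythe variant.  An exactly zero statistic (identical
    absolute-deviation profiles) reports p = 1.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n_total = sum(g.size for g in groups)
    df = (len(groups) - 1, n_total - len(groups))
    devs = [np.abs(g - (np.mean(g) if center == "mean" else np.median(g)))
            for g in groups]
    if np.std(np.concatenate(devs)) == 0:
        return TestResult(statistic=0.0, p_value=1.0, df=df, test_name="levene")
    if all(np.std(d) == 0 for d in devs):
        # group spreads differ but are exact within groups (e.g. one
        # noiseless arm): the F statistic degenerates to infinity
        return TestResult(statistic=float("inf"), p_value=0.0, df=df,
                          test_name="levene")
    stat, p = stats.levene(*groups, center=center)
    return TestResult(statistic=float(stat), p_value=float(p), df=df,
                      test_name="levene")


def effect_tests(per_subject: pd.DataFrame, effect: str,
                 levene_center: str = "mean") -> pd.DataFrame:
    """rANOVA + Levene per (metric, method) for one effect column.

    ``per_subject`` is a long table with columns subject_id, metric,
    method, value, and the effect column (e.g. ``field_strength`` or
    ``vendor``).  Each (metric, method) cell is pivoted to a subjects x
    effect-levels table; subjects with missing levels are dropped by the
    rANOVA.  The output mirrors a results table with the rANOVA p-value
    and the Levene p-value side by side.
    """
    required = {"subject_id", "metric", "method", "value", effect}
    missing = required - set(per_subject.columns)
    if missing:
        raise ValueError(f"per-subject table is missing columns: {sorted(missing)}")
    rows = []
    for (metric, method), grp in per_subject.groupby(["metric", "method"]):
        wide = grp.pivot_table(index="subject_id", columns=effect, values="value",
                               aggfunc="mean")
        if wide.shape[1] < 2:
            continue
        anova = ranova_oneway(wide)
        lev = levene([wide[c].dropna().to_numpy() for c in wide.columns],
                     center=levene_center)
        rows.append({"metric": metric, "method": method, "effect": effect,
                     "n_levels": wide.shape[1],
                     "ranova_F": anova.statistic, "ranova_p": anova.p_value,
                     "levene_W": lev.statistic, "levene_p": lev.p_value})
    return pd.DataFrame(rows)
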