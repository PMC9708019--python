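"""Descriptive and inferential statistics for two-group cohort comparisons.

Continuous variables are summarized as mean ± SD or median (IQR) depending on
a Shapiro–Wilk normality gate (α = 0.05, both groups must pass for the
parametric branch), compared with Welch's t-test or the Mann–Whitney U test
accordingly. Categorical variables use the chi-square test when all expected
cell counts are at least 5 and Fisher's exact test otherwise (for tables wider
than 2x2 the exact p-value is approximated by a fixed-margin Monte-Carlo
permutation of the chi-square statistic). No multiple-testing correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import DEVICE_TYPES, NUMERIC_FEATURES

__all__ = ["GroupComparison", "compare_numeric", "compare_categorical", "summarize"]

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of one two-group comparison."""

    variable: str
    test: str  # "t" | "mann-whitney" | "chi-square" | "fisher"
    p_value: float
    summaries: tuple  # per-group (centre, spread) pairs or count tables
    summary_style: str  # "mean_sd" | "median_iqr" | "counts"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def compare_numeric(x_group, y_group, variable: str = "") -> GroupComparison:
    """Normality-gated two-group comparison of a continuous variable.

    Both groups normal by Shapiro–Wilk at α = 0.05: Welch's two-sided t-test
    with mean ± SD summaries; otherwise the two-sided Mann–Whitney U test with
    median (IQR) summaries.
    """
    x = np.asarray(x_group, dtype=float)
    y = np.asarray(y_group, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    normal = all(
        np.ptp(g) == 0 or stats.shapiro(g).pvalue >= SHAPIRO_ALPHA for g in (x, y)
    )
    if normal:
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
        summ = tuple((float(g.mean()), float(g.std(ddof=1))) for g in (x, y))
        return GroupComparison(variable, "t", p, summ, "mean_sd")
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    summ = tuple(
        (float(np.median(g)), (float(np.percentile(g, 25)), float(np.percentile(g, 75))))
        for g in (x, y)
    )
    return GroupComparison(variable, "mann-whitney", p, summ, "median_iqr")


def compare_categorical(
    contingency, variable: str = "", n_mc: int = 20000, seed: int = 0
) -> GroupComparison:
    """Chi-square (all expected counts >= 5) or Fisher's exact test on a 2xk table."""
    table = np.asarray(contingency, dtype=int)
    if table.ndim != 2 or table.size == 0 or table.sum() == 0:
        raise ValueError("contingency table must be a non-empty 2-D count array")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    expected = stats.contingency.expected_freq(table)
    if np.all(expected >= 5):
        p = float(stats.chi2_contingency(table, correction=False)[1])
        return GroupComparison(variable, "chi-square", p, (table,), "counts")
    if table.shape == (2, 2):
        p = float(stats.fisher_exact(table)[1])
        return GroupComparison(variable, "fisher", p, (table,), "counts")
    # Fisher-style exact test on a wider table: Monte-Carlo over fixed-margin
    # tables, chi-square statistic as the ordering
    obs = stats.chi2_contingency(table, correction=False)[0]
    rng = np.random.default_rng(seed)
    samples = stats.random_table(table.sum(axis=1), table.sum(axis=0)).rvs(
        n_mc, random_state=rng
    )
    exceed = 0
    for s in samples:
        stat = np.nansum((s - expected) ** 2 / expected)
        if stat >= obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_mc + 1)
    return GroupComparison(variable, "fisher", float(p), (table,), "counts")


def summarize(cohort: pd.DataFrame, outcome: str = "ca") -> pd.DataFrame:
    """Population-table-style report: all / outcome+ / outcome- columns with p-values.

    One row per variable with gated summaries (``mean ± sd`` or
    ``median (q25–q75)``) and the comparison p-value; the device category row
    reports counts (%) per group. With a single outcome group, p-values are
    omitted.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    two_groups = outcome in cohort.columns and cohort[outcome].nunique() > 1
    g1 = cohort[cohort[outcome] == 1] if two_groups else cohort
    g0 = cohort[cohort[outcome] == 0] if two_groups else cohort

    def fmt(comp_style, centre, spread):
        if comp_style == "mean_sd":
            return f"{centre:.2f} ± {spread:.2f}"
        return f"{centre:.2f} ({spread[0]:.2f}–{spread[1]:.2f})"

    n = len(cohort)
    header = {
        "all": f"N = {n}",
        "pos": f"N = {len(g1)} ({100 * len(g1) / n:.0f}%)" if two_groups else "",
        "neg": f"N = {len(g0)} ({100 * len(g0) / n:.0f}%)" if two_groups else "",
    }
    rows = [{"variable": outcome, **header, "test": "", "p_value": np.nan}]
    feats = [f for f in ["annular_diameter"] + NUMERIC_FEATURES if f in cohort.columns]
    for feat in feats:
        if two_groups:
            comp = compare_numeric(g1[feat], g0[feat], variable=feat)
            all_comp_style = comp.summary_style
            if all_comp_style == "mean_sd":
                s_all = fmt("mean_sd", cohort[feat].mean(), cohort[feat].std(ddof=1))
            else:
                s_all = fmt(
                    "median_iqr", cohort[feat].median(),
                    (cohort[feat].quantile(0.25), cohort[feat].quantile(0.75)),
                )
            rows.append({
                "variable": feat,
                "all": s_all,
                "pos": fmt(comp.summary_style, *comp.summaries[0]),
                "neg": fmt(comp.summary_style, *comp.summaries[1]),
                "test": comp.test,
                "p_value": comp.p_value,
            })
        else:
            rows.append({
                "variable": feat,
                "all": fmt("mean_sd", cohort[feat].mean(), cohort[feat].std(ddof=1)),
                "pos": "", "neg": "", "test": "", "p_value": np.nan,
            })
    if "device_type" in cohort.columns:
        if two_groups:
            table = np.array([
                [int((g1["device_type"] == d).sum()) for d in DEVICE_TYPES],
                [int((g0["device_type"] == d).sum()) for d in DEVICE_TYPES],
            ])
            keep = table.sum(axis=0) > 0
            comp = compare_categorical(table[:, keep], variable="device_type")
            dev_p, dev_test = comp.p_value, comp.test
        else:
            dev_p, dev_test = np.nan, ""
        for d in DEVICE_TYPES:
            c_all = int((cohort["device_type"] == d).sum())
            row = {
                "variable": f"device:{d}",
                "all": f"{c_all} ({100 * c_all / n:.0f}%)",
                "test": dev_test if d == DEVICE_TYPES[0] else "",
                "p_value": dev_p if d == DEVICE_TYPES[0] else np.nan,
            }
            if two_groups:
                c1 = int((g1["device_type"] == d).sum())
                c0 = int((g0["device_type"] == d).sum())
                row["pos"] = f"{c1} ({100 * c1 / len(g1):.0f}%)"
                row["neg"] = f"{c0} ({100 * c0 / len(g0):.0f}%)"
            else:
                row["pos"] = row["neg"] = ""
            rows.append(row)
    return pd.DataFrame(rows)
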