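"""Descriptive statistics for the visit counts by covariate level.

Per level: n, percent, mean visits, SE = SD/sqrt(n) (n-1 denominator SD) and
a normal 95% CI (mean +/- 1.96 SE).  Association between a categorical
covariate and the count outcome is tested with the classical equal-variance
one-way ANOVA; for two-level covariates the pooled t-test is the same test
(F = t^2).  Significance stars follow the convention ***p<0.01, **p<0.05,
*p<0.10 with strict inequalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DescriptiveRow",
    "group_summary",
    "oneway_anova",
    "two_sample_t",
    "significance_stars",
    "describe_table",
]

Z95 = 1.96


@dataclass
class DescriptiveRow:
    variable: str
    level: str
    n: int
    pct: float
    mean: float
    se: float
    ci_low: float
    ci_high: float


def group_summary(y, group, variable: str = "") -> list[DescriptiveRow]:
    """Per-level n/%/mean/SE/95% CI, levels in order of first appearance.

    A level with a single subject has no sample SD; its row is emitted with
    NaN SE and CI plus a warning.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    if y.shape[0] != group.shape[0]:
        raise ValueError("y and group must have equal length")
    total = y.shape[0]
    levels = pd.unique(group)
    rows = []
    for level in levels:
        mask = group == level
        vals = y[mask]
        n = int(mask.sum())
        mean = float(vals.mean())
        if n >= 2:
            se = float(vals.std(ddof=1) / np.sqrt(n))
            lo, hi = mean - Z95 * se, mean + Z95 * se
        else:
            warnings.warn(f"level {level!r} has n=1; SE/CI undefined")
            se = lo = hi = float("nan")
        rows.append(
            DescriptiveRow(
                variable=variable,
                level=str(level),
                n=n,
                pct=100.0 * n / total,
                mean=mean,
                se=se,
                ci_low=lo,
                ci_high=hi,
            )
        )
    return rows


def oneway_anova(y, group):
    """Classical equal-variance one-way ANOVA across the observed levels.

    Returns ``(F, df1, df2, p)``.  Empty levels cannot occur (levels are
    taken from the data); with exactly two levels F equals the square of the
    pooled-variance t statistic.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = pd.unique(group)
    samples = [y[group == lv] for lv in levels]
    samples = [s for s in samples if s.size > 0]
    if len(samples) < 2:
        raise ValueError("need at least 2 non-empty levels")
    F, p = stats.f_oneway(*samples)
    df1 = len(samples) - 1
    df2 = y.shape[0] - len(samples)
    # identical groups give 0/0 in scipy; the data show no effect
    if not np.isfinite(F):
        F, p = 0.0, 1.0
    return float(F), df1, df2, float(p)


def two_sample_t(y, group):
    """Pooled-variance two-sample t-test for a binary covariate."""
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError("two_sample_t requires exactly 2 levels")
    t, p = stats.ttest_ind(y[group == levels[0]], y[group == levels[1]], equal_var=True)
    if not np.isfinite(t):
        t, p = 0.0, 1.0
    return float(t), float(p)


def significance_stars(p: float) -> str:
    """Star coding with strict thresholds: ***<0.01, **<0.05, *<0.10."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def describe_table(
    table: pd.DataFrame, outcome: str, covariates: list[str]
) -> pd.DataFrame:
    """Full descriptive table: one block of rows per covariate.

    The omnibus ANOVA p-value of each covariate (t-test and ANOVA coincide
    for two levels) supplies the significance stars, attached to every row
    of the block.
    """
    y = table[outcome].to_numpy()
    out = []
    for cov in covariates:
        group = table[cov].to_numpy()
        _, _, _, p = oneway_anova(y, group)
        star = significance_stars(p)
        for row in group_summary(y, group, variable=cov):
            out.append(
                {
                    "variable": cov,
                    "level": row.level,
                    "n": row.n,
                    "pct": round(row.pct, 1),
                    "mean": round(row.mean, 2),
                    "se": round(row.se, 3),
                    "ci_low": round(row.ci_low, 2),
                    "ci_high": round(row.ci_high, 2),
                    "p_anova": p,
                    "stars": star,
                }
            )
    return pd.DataFrame(out)
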