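"""Shared statistical contracts: mean +/- SEM, t-tests, ANOVA, bootstrap.

Conventions follow common practice in preclinical reports: data summarized
as mean +/- SEM, Welch's unequal-variance two-tailed t-test by default (a
pooled-variance switch is provided; the one-way-ANOVA F = t^2 identity holds
for the pooled variant), one-way ANOVA for simple group comparisons and
type-II two-way ANOVA for group x time designs, and no multiple-testing
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "GroupSummary",
    "group_summary",
    "ttest_two_tailed",
    "anova_oneway",
    "anova_twoway",
    "bootstrap",
]


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    sem: float


def group_summary(values, label: str = "") -> GroupSummary:
    """Mean +/- SEM summary (SD is the n-1 sample SD; SEM = SD/sqrt(n))."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("empty sample")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return GroupSummary(label=label, n=int(v.size), mean=float(v.mean()),
                        sd=sd, sem=sd / np.sqrt(v.size))


def ttest_two_tailed(a, b, pooled: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test.

    Welch's unequal-variance form by default; ``pooled=True`` gives the
    classical equal-variance test. Two zero-variance samples with equal
    means return (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = scipy.stats.ttest_ind(a, b, equal_var=pooled)
    return float(t), float(p)


def anova_oneway(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p over two or more groups."""
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    f, p = scipy.stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


def anova_twoway(table: pd.DataFrame, response: str, factor_a: str,
                 factor_b: str, interaction: bool = True) -> pd.DataFrame:
    """Two-way ANOVA with type-II sums of squares (statsmodels).

    Returns the ANOVA table indexed by effect, with sum_sq, df, F, PR(>F).
    Works on unbalanced layouts (type-II SS do not depend on factor order).
    """
    for col in (response, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if table[factor_a].nunique() < 2 or table[factor_b].nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")
    op = "*" if interaction else "+"
    model = ols(f"Q('{response}') ~ C(Q('{factor_a}')) {op} "
                f"C(Q('{factor_b}'))", data=table).fit()
    return sm.stats.anova_lm(model, typ=2)


def bootstrap(values, statistic, n_resamples: int = 2000,
              seed: int = 0) -> np.ndarray:
    """Seeded nonparametric bootstrap distribution of a statistic."""
    v = np.asarray(values)
    rng = np.random.default_rng(seed)
    return np.array([statistic(rng.choice(v, size=v.size, replace=True))
                     for _ in range(n_resamples)])
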