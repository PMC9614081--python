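"""Descriptive survey statistics and the Cochran–Armitage trend test.

Prevalence estimates come with Wilson score intervals (Clopper–Pearson
available by option); trends in a binary status across ordered survey
waves are tested with the Cochran–Armitage statistic using ordinal wave
scores 1..k by default (calendar-year scores available by option).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PrevalenceEstimate",
    "TrendTestResult",
    "prevalence_ci",
    "cochran_armitage",
    "describe_by_group",
]


@dataclass(frozen=True)
class PrevalenceEstimate:
    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    method: str = "wilson"
    stratum: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TrendTestResult:
    z: float
    pvalue: float
    scores: tuple
    degenerate: bool = False


def prevalence_ci(k: int, n: int, method: str = "wilson",
                  alpha: float = 0.05, **stratum) -> PrevalenceEstimate:
    """Proportion k/n with a 95% (by default) confidence interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be between 0 and n")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
    low, high = proportion_confint(k, n, alpha=alpha, method=sm_method)
    return PrevalenceEstimate(k=int(k), n=int(n), proportion=k / n,
                              ci_low=float(low), ci_high=float(high),
                              method=method, stratum=stratum)


def cochran_armitage(successes: Sequence[int], totals: Sequence[int],
                     scores: Optional[Sequence[float]] = None) -> TrendTestResult:
    """Cochran–Armitage test for trend in proportions across ordered groups.

    Z = sum_i s_i (x_i - n_i pbar) /
        sqrt( pbar (1-pbar) (sum n_i s_i^2 - (sum n_i s_i)^2 / N) )

    with group successes x_i, totals n_i, overall success fraction pbar,
    and group scores s_i (default 1..k).  Two-sided normal p-value.
    A degenerate table (all successes or all failures) returns p = 1 with
    the degenerate flag set.
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.shape != n.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need matched success/total vectors for >= 2 groups")
    if np.any(x < 0) or np.any(n <= 0) or np.any(x > n):
        raise ValueError("need 0 <= successes <= totals and positive totals")
    s = np.arange(1, len(x) + 1, dtype=float) if scores is None else np.asarray(
        scores, dtype=float)
    if s.shape != x.shape:
        raise ValueError("scores must match the number of groups")
    N = n.sum()
    pbar = x.sum() / N
    if pbar in (0.0, 1.0):
        return TrendTestResult(z=0.0, pvalue=1.0, scores=tuple(s), degenerate=True)
    num = float(np.sum(s * (x - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / N)
    if var <= 0:
        return TrendTestResult(z=0.0, pvalue=1.0, scores=tuple(s), degenerate=True)
    z = num / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return TrendTestResult(z=float(z), pvalue=float(min(p, 1.0)), scores=tuple(s))


def describe_by_group(df: pd.DataFrame, group: str,
                      continuous: Sequence[str] = (),
                      categorical: Sequence[str] = (),
                      yates: bool = False) -> pd.DataFrame:
    """Mean (SD) / N (%) descriptive table with across-group tests.

    Continuous variables get one-way ANOVA; categorical ones a Pearson
    chi-squared test (no continuity correction unless ``yates``).  Groups
    with no observations for a variable are dropped with a warning.
    Returns one row per variable (or variable level) in a long layout.
    """
    import warnings

    if group not in df.columns:
        raise ValueError(f"grouping column {group!r} not in frame")
    levels = sorted(df[group].dropna().unique())
    rows = []
    for var in continuous:
        sub = df[[group, var]].dropna()
        samples, kept = [], []
        for g in levels:
            vals = sub.loc[sub[group] == g, var].to_numpy(dtype=float)
            if len(vals) == 0:
                warnings.warn(f"{var}: group {g} empty, dropped")
                continue
            samples.append(vals)
            kept.append(g)
        if len(samples) >= 2 and all(len(v) >= 2 for v in samples):
            f, p = stats.f_oneway(*samples)
        else:
            f, p = np.nan, np.nan
        for g, vals in zip(kept, samples):
            rows.append({"variable": var, "level": "", "group": g,
                         "n": len(vals), "mean": vals.mean(),
                         "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                         "percent": np.nan, "stat": f, "pvalue": p,
                         "test": "anova"})
    for var in categorical:
        sub = df[[group, var]].dropna()
        table = pd.crosstab(sub[var], sub[group])
        table = table.loc[:, [g for g in levels if g in table.columns]]
        if table.shape[0] >= 2 and table.shape[1] >= 2 and (table.to_numpy().sum(axis=0) > 0).all():
            chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
        else:
            chi2, p = np.nan, np.nan
        col_n = table.sum(axis=0)
        for level in table.index:
            for g in table.columns:
                rows.append({"variable": var, "level": str(level), "group": g,
                             "n": int(table.loc[level, g]), "mean": np.nan,
                             "sd": np.nan,
                             "percent": 100.0 * table.loc[level, g] / col_n[g],
                             "stat": chi2, "pvalue": p, "test": "chi2"})
    return pd.DataFrame(rows)
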