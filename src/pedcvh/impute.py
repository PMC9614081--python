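"""Chained-equation multiple imputation and Rubin's-rules pooling.

Missing covariates are filled by iterating per-variable conditional
models over the incomplete columns (MICE): Bayesian-flavored draws are
obtained by refitting each conditional model on a bootstrap resample of
the observed rows before predicting, so that between-imputation variance
is positive.  Continuous variables use normal-model draws by default
(predictive mean matching available), binary variables logistic draws,
and multi-level categoricals multinomial draws (the latter two fitted
with scikit-learn).  Downstream per-imputation estimates are combined
with Rubin's rules: pooled point estimate = mean, total variance =
within + (1 + 1/m) x between, small-sample degrees of freedom per
Barnard–Rubin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ImputationConfig", "PooledEstimate", "impute_chained", "pool_rubin"]


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for chained imputation.

    m: number of completed datasets (study default 30).
    iterations: chained passes per dataset (default 10).
    methods: optional per-column override among
        {"norm", "pmm", "logistic", "multinomial"}.
    """

    m: int = 30
    iterations: int = 10
    seed: int = 0
    methods: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float        # Rubin pooled point estimate (Q-bar)
    within: float          # mean within-imputation variance (W-bar)
    between: float         # between-imputation variance (B)
    variance: float        # total variance T = W + (1 + 1/m) B
    m: int
    df: float
    ci_low: float
    ci_high: float
    pvalue: float


def pool_rubin(estimates: Sequence[float], variances: Sequence[float],
               alpha: float = 0.05) -> PooledEstimate:
    """Combine m per-imputation (estimate, variance) pairs.

    Uses the Barnard–Rubin degrees of freedom
    df = (m - 1) (1 + W / ((1 + 1/m) B))^2, infinite when B = 0.
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    if q.shape != w.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be matched 1-d sequences")
    m = len(q)
    if m < 2:
        raise ValueError("need at least 2 imputations to pool")
    qbar = float(q.mean())
    wbar = float(w.mean())
    b = float(q.var(ddof=1))
    t = wbar + (1 + 1 / m) * b
    if b > 0:
        with np.errstate(over="ignore"):
            df = float((m - 1) * (1.0 + np.float64(wbar) / ((1 + 1 / m) * b)) ** 2)
    else:
        df = np.inf
    se = np.sqrt(t)
    if se > 0:
        tcrit = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else stats.norm.ppf(
            1 - alpha / 2)
        ci = (qbar - tcrit * se, qbar + tcrit * se)
        stat = qbar / se
        p = 2 * (stats.t.sf(abs(stat), df) if np.isfinite(df) else stats.norm.sf(abs(stat)))
    else:
        ci = (qbar, qbar)
        p = np.nan
    return PooledEstimate(estimate=qbar, within=wbar, between=b, variance=t,
                          m=m, df=float(df), ci_low=float(ci[0]),
                          ci_high=float(ci[1]), pvalue=float(p))


# ---------------------------------------------------------------------------
# Chained imputation
# ---------------------------------------------------------------------------

def _infer_method(s: pd.Series) -> str:
    obs = s.dropna()
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        return "multinomial"
    vals = set(pd.unique(obs))
    if vals <= {0, 1, 0.0, 1.0, True, False}:
        return "logistic"
    return "norm"


def _encode_predictors(df: pd.DataFrame, exclude: str) -> np.ndarray:
    """Numeric design matrix (with intercept) from all columns but
    ``exclude``; object columns are dummy-coded."""
    parts = [np.ones((len(df), 1))]
    for col in df.columns:
        if col == exclude:
            continue
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.dropna()), key=str)[1:]
            for lev in levels:
                parts.append((s == lev).to_numpy(dtype=float)[:, None])
        else:
            parts.append(s.to_numpy(dtype=float)[:, None])
    return np.hstack(parts)


def _draw_continuous(X_obs, y_obs, X_mis, rng, pmm: bool):
    nb = rng.integers(0, len(y_obs), size=len(y_obs))
    Xb, yb = X_obs[nb], y_obs[nb]
    beta, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
    resid = yb - Xb @ beta
    dof = max(len(yb) - Xb.shape[1], 1)
    sigma = np.sqrt(float(resid @ resid) / dof)
    pred_mis = X_mis @ beta
    if pmm:
        pred_obs = X_obs @ beta
        k = min(5, len(y_obs))
        out = np.empty(len(pred_mis))
        order = np.argsort(pred_obs)
        sorted_pred = pred_obs[order]
        for i, pm in enumerate(pred_mis):
            pos = np.searchsorted(sorted_pred, pm)
            lo = max(0, pos - k)
            hi = min(len(sorted_pred), pos + k)
            cand = order[lo:hi]
            cand = cand[np.argsort(np.abs(pred_obs[cand] - pm))][:k]
            out[i] = y_obs[cand[rng.integers(0, len(cand))]]
        return out
    return pred_mis + rng.normal(0.0, sigma, size=len(pred_mis))


def _draw_classifier(X_obs, y_obs, X_mis, rng, multinomial: bool):
    from sklearn.linear_model import LogisticRegression

    nb = rng.integers(0, len(y_obs), size=len(y_obs))
    Xb, yb = X_obs[nb], y_obs[nb]
    classes = pd.unique(yb)
    if len(classes) < 2:
        # bootstrap collapsed to one class: impute it everywhere
        return np.full(len(X_mis), classes[0], dtype=object)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(penalty=None, max_iter=500)
        clf.fit(Xb[:, 1:], yb.astype(str))
        prob = clf.predict_proba(X_mis[:, 1:])
    cum = prob.cumsum(axis=1)
    u = rng.random(len(X_mis))[:, None]
    idx = (u > cum).sum(axis=1)
    drawn = np.asarray(clf.classes_, dtype=object)[idx]
    if not multinomial:
        lookup = {str(v): v for v in pd.unique(y_obs)}
        drawn = np.asarray([lookup[d] for d in drawn], dtype=object)
        return drawn
    return drawn


def impute_chained(df: pd.DataFrame, config: ImputationConfig,
                   columns: Optional[Sequence[str]] = None) -> list[pd.DataFrame]:
    """Produce ``config.m`` completed copies of ``df``.

    Only ``columns`` (default: every column with missing values) are
    imputed; all columns of ``df`` serve as predictors in the conditional
    models.  Observed values are never altered.  Deterministic for a
    fixed ``(df, config)``.
    """
    df = df.copy()
    if columns is None:
        columns = [c for c in df.columns if df[c].isna().any()]
    columns = list(columns)
    for c in columns:
        if df[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing; "
                             "conditional model inestimable")
    incomplete = [c for c in columns if df[c].isna().any()]
    if not incomplete:
        return [df.copy() for _ in range(config.m)]

    methods = {c: config.methods.get(c, _infer_method(df[c])) for c in incomplete}
    miss_mask = {c: df[c].isna().to_numpy() for c in incomplete}
    streams = np.random.SeedSequence(config.seed).spawn(config.m)
    results = []
    for chain in range(config.m):
        rng = np.random.default_rng(streams[chain])
        work = df.copy()
        # initialize by sampling observed values
        for c in incomplete:
            obs = work[c].dropna().to_numpy()
            fill = obs[rng.integers(0, len(obs), size=int(miss_mask[c].sum()))]
            work.loc[miss_mask[c], c] = fill
        for _ in range(config.iterations):
            for c in incomplete:
                mis = miss_mask[c]
                Xall = _encode_predictors(work, exclude=c)
                X_obs, X_mis = Xall[~mis], Xall[mis]
                method = methods[c]
                if method in ("norm", "pmm"):
                    y_obs = df.loc[~mis, c].to_numpy(dtype=float)
                    drawn = _draw_continuous(X_obs, y_obs, X_mis, rng,
                                             pmm=(method == "pmm"))
                elif method in ("logistic", "multinomial"):
                    y_obs = df.loc[~mis, c].to_numpy()
                    drawn = _draw_classifier(X_obs, y_obs, X_mis, rng,
                                             multinomial=(method == "multinomial"))
                    if method == "logistic" and df[c].dtype != object:
                        drawn = pd.to_numeric(pd.Series(drawn)).to_numpy()
                else:
                    raise ValueError(f"unknown imputation method {method!r}")
                work.loc[mis, c] = drawn
        for c in incomplete:
            if df[c].dtype != object:
                work[c] = pd.to_numeric(work[c])
        results.append(work)
    return results
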