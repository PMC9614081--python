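"""Multivariable logistic regression and population attributable risk.

The logistic model is fitted by iteratively reweighted least squares
(IRLS) with Wald confidence intervals, the standard reporting choice for
odds ratios.  The population attributable fraction (PAR) of an exposure
for a binary outcome uses model-based standardization — one minus the
ratio of the mean predicted risk with the exposure set to its reference
level to the observed case fraction — with a seeded nonparametric
bootstrap for the interval.  Levin's and Miettinen's closed-form
estimators from 2x2 summaries are provided as validation companions; in
the unadjusted binary-exposure case model standardization coincides
exactly with Miettinen's formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .impute import PooledEstimate, pool_rubin

__all__ = [
    "LogisticFit",
    "PARResult",
    "SeparationError",
    "build_design",
    "fit_logistic",
    "par_model_standardization",
    "par_from_2x2",
    "run_association_suite",
]


class SeparationError(RuntimeError):
    """The likelihood is monotone (perfect separation); the MLE diverges."""


@dataclass
class LogisticFit:
    params: pd.Series            # log-odds coefficients, incl. intercept
    bse: pd.Series               # standard errors (observed information)
    deviance: float
    iterations: int
    n: int
    converged: bool

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        or_ = np.exp(self.params)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        wald = self.params / self.bse
        p = 2 * stats.norm.sf(np.abs(wald))
        return pd.DataFrame({"coef": self.params, "se": self.bse, "OR": or_,
                             "ci_low": lo, "ci_high": hi, "pvalue": p})

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = X.to_numpy(dtype=float) @ self.params.reindex(X.columns).to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def build_design(df: pd.DataFrame, predictors: Sequence[str],
                 reference: Optional[dict] = None,
                 add_intercept: bool = True) -> pd.DataFrame:
    """Reference-coded design matrix.

    Numeric / boolean columns enter as-is; object/categorical columns are
    dummy-coded dropping the reference level (``reference[col]`` if given,
    else the first level in sorted order).
    """
    reference = reference or {}
    parts = []
    if add_intercept:
        parts.append(pd.Series(1.0, index=df.index, name="intercept"))
    for col in predictors:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.dropna().unique(), key=str)
            ref = reference.get(col, levels[0] if levels else None)
            for lev in levels:
                if lev == ref:
                    continue
                parts.append((s == lev).astype(float).rename(f"{col}[{lev}]"))
        else:
            parts.append(pd.to_numeric(s).astype(float).rename(col))
    return pd.concat(parts, axis=1)


def fit_logistic(y, X: pd.DataFrame, tol: float = 1e-8,
                 max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS.

    Converges on the change in deviance (< ``tol``).  Raises
    ``SeparationError`` when coefficients diverge (perfect separation) and
    ``ValueError`` naming collinear columns on a rank-deficient design.
    """
    ynum = np.asarray(y, dtype=float)
    if set(np.unique(ynum)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    if n <= p:
        raise ValueError("need more observations than parameters")
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(Xm, pivoting=True, mode="economic")
        bad = sorted(X.columns[piv[rank:]])
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")

    beta = np.zeros(p)
    dev_old = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xm @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu * (1 - mu)
        z = eta + (ynum - mu) / w
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(Xm * sw[:, None], z * sw, rcond=None)
        dev = -2.0 * float(np.sum(ynum * np.log(mu) + (1 - ynum) * np.log(1 - mu)))
        if np.max(np.abs(beta)) > 30:
            raise SeparationError(
                "coefficients diverging; data likely perfectly separated")
        if abs(dev_old - dev) < tol:
            dev_old = dev
            break
        dev_old = dev
    eta = Xm @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    w = mu * (1 - mu)
    info = (Xm * w[:, None]).T @ Xm
    cov = np.linalg.inv(info)
    dev = -2.0 * float(np.sum(ynum * np.log(mu) + (1 - ynum) * np.log(1 - mu)))
    return LogisticFit(
        params=pd.Series(beta, index=X.columns),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=X.columns),
        deviance=dev, iterations=it, n=n,
        converged=abs(dev_old - dev) < max(tol, 1e-6) or it < max_iter,
    )


@dataclass(frozen=True)
class PARResult:
    estimate: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    estimator: str = "model_standardization"
    exposure: str = ""
    n_bootstrap: int = 0


def _af_standardized(y, X, exposure_cols) -> float:
    fit = fit_logistic(y, X)
    X0 = X.copy()
    for c in exposure_cols:
        X0[c] = 0.0
    risk0 = fit.predict(X0).mean()
    observed = float(np.mean(y))
    if observed == 0:
        raise ValueError("no cases; attributable fraction undefined")
    return 1.0 - risk0 / observed


def par_model_standardization(y, X: pd.DataFrame, exposure: str | Sequence[str],
                              n_bootstrap: int = 500, seed: int = 0,
                              alpha: float = 0.05) -> PARResult:
    """Attributable fraction of ``exposure`` by model standardization.

    AF = 1 - mean(predicted risk with exposure at reference) / observed
    case fraction, from a logistic fit on ``X``.  ``exposure`` names the
    design column(s) (dummy indicators) set to zero in the counterfactual.
    CI by seeded nonparametric bootstrap (percentile method).
    """
    exposure_cols = [exposure] if isinstance(exposure, str) else list(exposure)
    for c in exposure_cols:
        if c not in X.columns:
            raise ValueError(f"exposure column {c!r} not in design")
    y = np.asarray(y, dtype=float)
    est = _af_standardized(y, X, exposure_cols)
    if n_bootstrap <= 0:
        return PARResult(estimate=est, estimator="model_standardization",
                         exposure=",".join(exposure_cols))
    rng = np.random.default_rng(seed)
    n = len(y)
    reps = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            reps.append(_af_standardized(y[idx], X.iloc[idx].reset_index(drop=True),
                                         exposure_cols))
        except (SeparationError, ValueError, np.linalg.LinAlgError):
            continue
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return PARResult(estimate=est, ci_low=float(lo), ci_high=float(hi),
                     estimator="model_standardization",
                     exposure=",".join(exposure_cols), n_bootstrap=len(reps))


def par_from_2x2(a: float, b: float, c: float, d: float,
                 kind: str = "levin") -> PARResult:
    """Closed-form attributable fraction from a 2x2 table.

    ``a`` exposed cases, ``b`` exposed non-cases, ``c`` unexposed cases,
    ``d`` unexposed non-cases.  Levin uses overall exposure prevalence,
    Miettinen exposure prevalence among cases.
    """
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise ValueError("all margins of the 2x2 table must be positive")
    n = a + b + c + d
    risk1 = a / (a + b)
    risk0 = c / (c + d)
    if risk0 == 0:
        raise ValueError("zero risk in the unexposed; RR undefined")
    rr = risk1 / risk0
    if kind == "levin":
        pe = (a + b) / n
        af = pe * (rr - 1) / (1 + pe * (rr - 1))
    elif kind == "miettinen":
        pc = a / (a + c)
        af = pc * (rr - 1) / rr
    else:
        raise ValueError("kind must be 'levin' or 'miettinen'")
    return PARResult(estimate=float(af), estimator=kind, exposure="2x2")


def run_association_suite(imputed: Sequence[pd.DataFrame], outcome: str,
                          predictors: Sequence[str],
                          reference: Optional[dict] = None,
                          par_exposure: Optional[str] = None,
                          par_bootstrap: int = 0, seed: int = 0,
                          alpha: float = 0.05) -> dict:
    """Fit the logistic model on each imputed dataset and pool.

    Per-imputation coefficients are pooled with Rubin's rules on the
    log-odds scale; odds ratios and their CIs are the exponentials of the
    pooled quantities.  When ``par_exposure`` is given (a design column),
    the standardized attributable fraction is computed per imputation and
    pooled the same way (bootstrap variance within imputation).

    Returns ``{"or_table": DataFrame, "par": PooledEstimate | None}``.
    """
    m = len(imputed)
    if m == 0:
        raise ValueError("no imputed datasets")
    coefs, ses = [], []
    pars, par_vars = [], []
    for i, data in enumerate(imputed):
        sub = data.dropna(subset=[outcome])
        y = pd.to_numeric(sub[outcome]).astype(float).to_numpy()
        X = build_design(sub, predictors, reference=reference)
        try:
            fit = fit_logistic(y, X)
        except Exception as exc:
            raise RuntimeError(f"logistic fit failed on imputation {i}: {exc}") from exc
        coefs.append(fit.params)
        ses.append(fit.bse)
        if par_exposure is not None:
            res = par_model_standardization(y, X, par_exposure,
                                            n_bootstrap=par_bootstrap,
                                            seed=seed + i)
            pars.append(res.estimate)
            if par_bootstrap > 0:
                par_vars.append(((res.ci_high - res.ci_low)
                                 / (2 * stats.norm.ppf(1 - alpha / 2))) ** 2)
            else:
                par_vars.append(0.0)
    coef_df = pd.DataFrame(coefs)
    se_df = pd.DataFrame(ses)
    z = stats.norm.ppf(1 - alpha / 2)
    rows = {}
    for term in coef_df.columns:
        if m >= 2:
            pooled = pool_rubin(coef_df[term].to_numpy(),
                                se_df[term].to_numpy() ** 2, alpha=alpha)
            coef, se = pooled.estimate, np.sqrt(pooled.variance)
            lo, hi, p, df = (pooled.ci_low, pooled.ci_high, pooled.pvalue,
                             pooled.df)
        else:  # single (complete-case) fit: plain Wald summaries
            coef, se = float(coef_df[term].iloc[0]), float(se_df[term].iloc[0])
            lo, hi = coef - z * se, coef + z * se
            p, df = 2 * stats.norm.sf(abs(coef / se)), np.inf
        with np.errstate(over="ignore"):
            rows[term] = {
                "coef": coef, "se": se, "OR": np.exp(coef),
                "ci_low": np.exp(lo), "ci_high": np.exp(hi),
                "pvalue": p, "df": df, "m": m,
            }
    out = {"or_table": pd.DataFrame(rows).T, "par": None}
    if par_exposure is not None:
        if m >= 2:
            out["par"] = pool_rubin(np.asarray(pars), np.asarray(par_vars))
        else:
            out["par"] = PooledEstimate(
                estimate=pars[0], within=par_vars[0], between=0.0,
                variance=par_vars[0], m=1, df=np.inf,
                ci_low=pars[0] - 1.96 * np.sqrt(par_vars[0]),
                ci_high=pars[0] + 1.96 * np.sqrt(par_vars[0]),
                pvalue=np.nan)
    return out
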