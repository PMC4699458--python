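"""Frequentist analysis stage: baseline tests, per-imputation GLMs and
Rubin's-rules pooling.

Two response families are supported for the arm-effect models:

* ``normal-identity`` — ordinary least squares with classical SEs; with a
  single binary covariate the arm coefficient is exactly the difference of
  group means.
* ``poisson-log`` — quasi-Poisson scoring (IRLS) on a non-negative
  continuous response.  Under the log link the arm coefficient equals the
  log of the ratio of fitted group means.  Two codings of a percentage
  response are available: ``percent`` (100·proportion, the default) and
  ``log100`` (ln(100·proportion)).

Estimates from the ``m`` imputed datasets are combined by Rubin's rules:
Qbar = mean(Q_i), Ubar = mean(SE_i^2), B = var(Q_i),
T = Ubar + (1 + 1/m) B, with the Rubin/Schenker small-m degrees of
freedom  (m-1)(1 + Ubar/((1+1/m)B))^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .impute import ImputationSet

FAMILIES = ("normal-identity", "poisson-log")


@dataclass
class TTestResult:
    t: float
    df: float
    p_value: float
    bonferroni_significant: bool | None = None

    def __repr__(self):
        return f"TTestResult(t={self.t:.4f}, df={self.df:.2f}, p={self.p_value:.4g})"


@dataclass
class FitResult:
    """One GLM fit on one complete dataset."""

    terms: list
    coef: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    family: str
    response: str
    n: int
    dispersion: float = 1.0
    df_resid: float = np.nan
    loglik: float = np.nan

    def to_frame(self):
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "p": self.p_values}, index=self.terms
        )


@dataclass
class PooledEstimate:
    """Rubin-combined coefficient with variance decomposition."""

    term: str
    qbar: float
    ubar: float
    b: float
    t_total: float
    df: float
    t_stat: float
    p_value: float
    m: int
    degenerate_b: bool = False

    @property
    def se(self):
        return float(np.sqrt(self.t_total))

    def ci(self, level=0.95):
        half = stats.t.ppf(0.5 + level / 2, self.df) * self.se
        return (self.qbar - half, self.qbar + half)


def welch_t(mean1, sd1, n1, mean2, sd2, n2) -> TTestResult:
    """Welch's unequal-variance two-sample t test from summary statistics."""
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    if min(sd1, sd2) <= 0:
        raise ValueError("SDs must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Family-wise significance flags: p_i < alpha / M with M = len(p_values)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    return p < alpha / p.size


def _ols(X, y):
    n, k = X.shape
    XtX = X.T @ X
    beta = linalg.solve(XtX, X.T @ y, assume_a="pos")
    resid = y - X @ beta
    dfr = n - k
    s2 = float(resid @ resid) / dfr
    cov = s2 * linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    ll = -0.5 * n * (np.log(2 * np.pi * (resid @ resid) / n) + 1)
    return beta, se, dfr, 1.0, float(ll)


def _quasipoisson_irls(X, y, max_iter=100, tol=1e-10):
    n, k = X.shape
    mu = np.clip(y, 1e-3, None) + 0.5
    eta = np.log(mu)
    beta = np.zeros(k)
    for _ in range(max_iter):
        W = mu  # canonical log link: working weight = mu
        z = eta + (y - mu) / mu
        XtW = X.T * W
        beta_new = linalg.solve(XtW @ X, XtW @ z, assume_a="pos")
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
    eta = X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    dfr = n - k
    pearson = float(np.sum((y - mu) ** 2 / mu))
    phi = pearson / dfr  # quasi-likelihood dispersion
    cov = phi * linalg.inv((X.T * mu) @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, dfr, phi


def design_from_frame(df: pd.DataFrame, covariates) -> tuple[np.ndarray, list]:
    """Intercept + requested covariates; 'arm' codes ART-Early as 1."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    for c in covariates:
        if c == "arm":
            cols.append((df["group"] == "ART-Early").to_numpy(float))
        elif c == "visit":
            cols.append((df["visit"] == 2).to_numpy(float))
        elif c == "visit_age":
            cols.append(df["age_days"].to_numpy(float))
        else:
            cols.append(df[c].to_numpy(float))
        names.append(c)
    return np.column_stack(cols), names


def glm_fit(table, response: str, family: str = "normal-identity",
            covariates=("arm",), response_coding: str = "percent",
            on_nonpositive: str = "error") -> FitResult:
    """Fit one GLM on a complete dataset (DataFrame or LongTable).

    ``response_coding`` applies to the poisson family only: ``percent``
    fits the response on its natural percent scale, ``log100`` fits
    ln(100·proportion) = ln(percent) as a literal transform.
    ``on_nonpositive`` controls log-link handling of non-positive
    responses: ``error`` (default) or ``shift`` (adds the minimum offset
    making all responses positive, recorded in the result's response
    label).
    """
    df = table.df if hasattr(table, "df") else table
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    y = df[response].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("glm_fit requires a complete response; impute first")
    X, names = design_from_frame(df, covariates)
    label = response
    if family == "normal-identity":
        beta, se, dfr, phi, ll = _ols(X, y)
        p = 2.0 * stats.t.sf(np.abs(beta / se), dfr)
    else:
        if response_coding == "log100":
            if (y <= 0).any():
                raise ValueError(
                    f"non-positive response values for {response!r}: cannot "
                    "apply the log100 coding"
                )
            y = np.log(y)  # response is percent = 100 * proportion
            label = f"log100({response})"
        if (y < 0).any():
            if on_nonpositive == "shift":
                shift = -y.min() + 1e-6
                y = y + shift
                label = f"{label}+{shift:.3g}"
            else:
                raise ValueError(
                    f"negative response values for {response!r} under log link"
                )
        beta, se, dfr, phi = _quasipoisson_irls(X, y)
        p = 2.0 * stats.t.sf(np.abs(beta / se), dfr)
        ll = np.nan
    return FitResult(names, beta, se, p, family, label, n=len(y),
                     dispersion=phi, df_resid=dfr, loglik=ll)


def rubin_pool(fits: list, term: str, df_complete: float | None = None) -> PooledEstimate:
    """Combine one coefficient across ``m`` imputation fits by Rubin's rules."""
    m = len(fits)
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 fits")
    terms0 = fits[0].terms
    if any(f.terms != terms0 for f in fits):
        raise ValueError("fits must share an identical model")
    j = terms0.index(term)
    Q = np.array([f.coef[j] for f in fits])
    U = np.array([f.se[j] ** 2 for f in fits])
    qbar = float(Q.mean())
    ubar = float(U.mean())
    b = float(Q.var(ddof=1))
    t_total = ubar + (1 + 1 / m) * b
    degenerate = b <= 0 or not np.isfinite(b)
    if degenerate:
        df = float(df_complete if df_complete is not None else fits[0].df_resid)
        t_total = ubar
    else:
        with np.errstate(over="ignore"):
            df = float(np.float64(m - 1) *
                       (1.0 + np.float64(ubar) / ((1 + 1 / m) * np.float64(b))) ** 2)
        df = min(df, 1e12)  # vanishing B: effectively complete-data df
    tstat = qbar / np.sqrt(t_total)
    p = 2.0 * float(stats.t.sf(abs(tstat), df))
    return PooledEstimate(term, qbar, ubar, b, float(t_total), float(df),
                          float(tstat), p, m, degenerate_b=degenerate)


class MIPooledGLM:
    """GLM over an :class:`ImputationSet`, pooled by Rubin's rules."""

    def __init__(self, imputations: ImputationSet, response: str,
                 family: str = "normal-identity", covariates=("arm",),
                 response_coding: str = "percent"):
        self.imputations = imputations
        self.response = response
        self.family = family
        self.covariates = tuple(covariates)
        self.response_coding = response_coding

    def fit(self) -> "MIPooledResults":
        fits = [
            glm_fit(t, self.response, self.family, self.covariates,
                    self.response_coding)
            for t in self.imputations.tables
        ]
        pooled = {term: rubin_pool(fits, term) for term in fits[0].terms}
        return MIPooledResults(self, fits, pooled)


class MIPooledResults:
    """Pooled coefficients, their variance decomposition, and a summary table."""

    def __init__(self, model, fits, pooled):
        self.model = model
        self.fits = fits
        self.pooled = pooled

    def __getitem__(self, term) -> PooledEstimate:
        return self.pooled[term]

    def predicted_mean(self, arm: str = "ART-Early", visit: int = 2) -> float:
        """Pooled fitted mean response for a covariate profile (link scale inverted)."""
        x = {"intercept": 1.0, "arm": float(arm == "ART-Early"),
             "visit": float(visit == 2)}
        eta = sum(self.pooled[t].qbar * x.get(t, 0.0) for t in self.pooled)
        return float(np.exp(eta)) if self.model.family == "poisson-log" else float(eta)

    def summary(self) -> pd.DataFrame:
        rows = []
        for term, pe in self.pooled.items():
            lo, hi = pe.ci()
            rows.append({"term": term, "coef": pe.qbar, "se": pe.se,
                         "t": pe.t_stat, "df": pe.df, "p": pe.p_value,
                         "ci_low": lo, "ci_high": hi, "B": pe.b, "Ubar": pe.ubar})
        return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# logistic regression + backward stepwise selection over imputations
# ---------------------------------------------------------------------------

def _logistic_irls(X, y, ridge=0.0, max_iter=100, tol=1e-10):
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = special.expit(eta)
        W = mu * (1 - mu)
        H = (X.T * W) @ X + ridge * np.eye(k)
        g = X.T @ (y - mu) - ridge * beta
        try:
            step = linalg.solve(H, g, assume_a="pos")
        except linalg.LinAlgError:
            step = np.linalg.pinv(H) @ g
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = special.expit(eta)
    ll = float(np.sum(y * np.log(np.clip(mu, 1e-12, 1)) +
                      (1 - y) * np.log(np.clip(1 - mu, 1e-12, 1))))
    H = (X.T * (mu * (1 - mu))) @ X + ridge * np.eye(k)
    cov = linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    separated = bool((mu > 1 - 1e-8).all() or (mu < 1e-8).all() or
                     np.max(np.abs(beta)) > 20)
    return beta, se, ll, separated


def _logistic_fit_result(df, outcome_col, candidates, ridge=0.0):
    y = df[outcome_col].to_numpy(float)
    X = np.column_stack([np.ones(len(df))] +
                        [df[c].to_numpy(float) for c in candidates])
    beta, se, ll, separated = _logistic_irls(X, y, ridge=ridge)
    if separated and ridge == 0.0:
        warnings.warn("separation detected; refitting with ridge penalty")
        beta, se, ll, _ = _logistic_irls(X, y, ridge=1e-2)
    terms = ["intercept"] + list(candidates)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return FitResult(terms, beta, se, p, "binomial-logit", outcome_col,
                     n=len(y), df_resid=len(y) - len(terms), loglik=ll), ll


def stepwise_logistic(imps: ImputationSet, candidates, outcome: str = "arm",
                      alpha_vote: float = 0.5) -> dict:
    """Backward AIC elimination per imputation, majority-vote final set.

    Within each completed dataset a logistic model of the arm indicator on
    the candidate variables is pruned greedily by AIC; variables retained
    in more than ``alpha_vote`` of the imputations form the final set,
    which is refit per imputation and Rubin-pooled.
    """
    if imps.m < 2:
        raise ValueError("need m >= 2 imputations")
    frames = []
    for t in imps.tables:
        df = t.df.copy() if hasattr(t, "df") else t.copy()
        if outcome == "arm":
            df["_outcome"] = (df["group"] == "ART-Early").astype(float)
        else:
            df["_outcome"] = df[outcome].to_numpy(float)
        frames.append(df)

    selected_sets = []
    for df in frames:
        current = list(candidates)
        _, ll = _logistic_fit_result(df, "_outcome", current)
        aic = 2 * (len(current) + 1) - 2 * ll
        improved = True
        while improved and current:
            improved = False
            best_drop, best_aic = None, aic
            for c in current:
                reduced = [x for x in current if x != c]
                _, ll_r = _logistic_fit_result(df, "_outcome", reduced)
                aic_r = 2 * (len(reduced) + 1) - 2 * ll_r
                if aic_r < best_aic:
                    best_drop, best_aic = c, aic_r
            if best_drop is not None:
                current.remove(best_drop)
                aic = best_aic
                improved = True
        selected_sets.append(set(current))

    votes = {c: sum(c in s for s in selected_sets) / imps.m for c in candidates}
    final = [c for c in candidates if votes[c] > alpha_vote]
    fits = [_logistic_fit_result(df, "_outcome", final)[0] for df in frames]
    pooled = {term: rubin_pool(fits, term) for term in fits[0].terms}
    return {"selected": final, "votes": votes, "pooled": pooled,
            "per_imputation_sets": selected_sets}
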