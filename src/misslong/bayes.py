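"""Full-Bayesian one-step models: MCMC jointly sampling the regression
parameters and the missing responses (data augmentation).

Normal mode is a conjugate Gibbs sampler for y = X b + e with
b ~ N(0, tau^2 I), tau = prior_scale_mult * SD(observed y), and
sigma^2 ~ InvGamma(0.001, 0.001); each sweep also draws the missing
responses from N(x_i'b, sigma^2).  Poisson mode rounds the percent-scale
response to counts and updates the coefficients with an adaptive
random-walk Metropolis step (target acceptance 20–40%), drawing missing
responses from Poisson(exp(x_i'b)).

Convergence is monitored with the Gelman-Rubin potential scale reduction
factor over >= 2 over-dispersed chains; model comparison uses the
Deviance Information Criterion DIC = Dbar + pD with pD = Dbar - D(theta_bar).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .glm import design_from_frame

DEFAULT_BURN_IN = 4000


@dataclass
class McmcConfig:
    n_iter: int = 100_000
    burn_in: int = DEFAULT_BURN_IN
    n_chains: int = 2
    thin: int = 1
    seed: int = 0
    proposal_scale: float = 0.1  # initial RW scale (Poisson mode), adapted in burn-in

    def validate(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ModelSpec:
    """Likelihood and (data-derived) prior choices."""

    likelihood: str = "normal-identity"
    prior_scale_mult: float = 10.0  # prior SD = mult * SD(observed response)
    prior_sd: float | None = None   # explicit prior SD (overrides the multiplier)
    fixed_sigma2: float | None = None  # known residual variance (normal mode)
    sigma_prior_shape: float = 0.001
    sigma_prior_rate: float = 0.001

    def validate(self):
        if self.likelihood not in ("normal-identity", "poisson-log"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.prior_scale_mult <= 0:
            raise ValueError("prior scale must be positive")
        if self.prior_sd is not None and self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if self.fixed_sigma2 is not None and self.fixed_sigma2 <= 0:
            raise ValueError("fixed_sigma2 must be positive")


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor from between/within chain variances.

    ``chains`` is (m, n) — m chains of n draws of one scalar.  Identical
    chains give exactly 1.0; values well above 1.1 flag non-convergence.
    """
    C = np.asarray(chains, float)
    if C.ndim != 2 or C.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = C.shape
    if n < 10:
        raise ValueError("chains too short for R-hat")
    W = C.var(axis=1, ddof=1).mean()
    if W <= 0:
        warnings.warn("zero within-chain variance; R-hat undefined")
        return np.nan
    B_over_n = C.mean(axis=1).var(ddof=1)  # var of chain means
    return float(np.sqrt(1.0 + (1 + 1 / m) * B_over_n / W))


def effective_sample_size(chains) -> float:
    """ESS via the autocorrelation sum with Geyer's initial-positive truncation."""
    C = np.asarray(chains, float)
    if C.ndim == 1:
        C = C[None, :]
    m, n = C.shape
    acsum = 0.0
    for c in C:
        x = c - c.mean()
        f = np.fft.rfft(x, 2 * n)
        acf = np.fft.irfft(f * np.conj(f))[:n]
        if acf[0] <= 0:
            continue
        acf = acf / acf[0]
        s = 0.0
        for t in range(1, n - 1, 2):
            pair = acf[t] + acf[t + 1]
            if pair < 0:
                break
            s += pair
        acsum += s
    tau = 1.0 + 2.0 * acsum / m
    return float(m * n / max(tau, 1e-12))


def dic(deviance_draws, deviance_at_mean) -> dict:
    """DIC = Dbar + pD with pD = Dbar - D(posterior mean)."""
    d = np.asarray(deviance_draws, float)
    if d.size < 2:
        raise ValueError("need >= 2 deviance draws")
    dbar = float(d.mean())
    pd_ = dbar - float(deviance_at_mean)
    return {"DIC": dbar + pd_, "Dbar": dbar, "pD": pd_}


@dataclass
class PosteriorSummary:
    """Per-coefficient posterior summaries plus model-level diagnostics."""

    terms: list
    mean: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    rhat: np.ndarray
    ess: np.ndarray
    p_values: np.ndarray  # Wald-style two-sided p from posterior mean/SD
    dic: dict
    converged: bool
    acceptance: float | None
    draws: np.ndarray = field(repr=False)  # (chains, draws, k)
    sigma_draws: np.ndarray | None = field(default=None, repr=False)
    imputed_draws: np.ndarray | None = field(default=None, repr=False)
    n_missing: int = 0

    def __getitem__(self, term):
        j = self.terms.index(term)
        return {"mean": self.mean[j], "sd": self.sd[j],
                "ci": (self.ci_low[j], self.ci_high[j]),
                "rhat": self.rhat[j], "ess": self.ess[j], "p": self.p_values[j]}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": self.mean, "sd": self.sd,
            "hdi_2.5%": self.ci_low, "hdi_97.5%": self.ci_high,
            "rhat": self.rhat, "ess": self.ess, "p": self.p_values,
        }, index=self.terms)


class BayesGLM:
    """One-step Bayesian GLM with missing-response augmentation.

    Parameters
    ----------
    table : LongTable or DataFrame
        Source rows; the response may contain NaN, covariates must not.
    response : str
        Response column.
    covariates : sequence
        Any of ``arm``, ``visit``, ``visit_age`` or numeric columns; an
        intercept is always included (empty sequence = intercept only).
    spec : ModelSpec
    """

    def __init__(self, table, response: str, covariates=("arm",),
                 spec: ModelSpec | None = None):
        df = table.df if hasattr(table, "df") else table
        self.spec = spec or ModelSpec()
        self.spec.validate()
        y = df[response].to_numpy(float)
        X, names = design_from_frame(df, covariates)
        if np.isnan(X).any():
            raise ValueError("covariates must be fully observed")
        self.obs = ~np.isnan(y)
        if self.obs.sum() < 2:
            raise ValueError("need at least 2 observed response values")
        if self.obs.sum() < 10:
            warnings.warn("fewer than 10 observed response values; posterior "
                          "summaries will be prior-sensitive")
        self.y = y
        self.X = X
        self.terms = names
        self.response = response
        if self.spec.likelihood == "poisson-log":
            self.y_obs = np.round(y[self.obs]).astype(float)  # percent-scale counts
            if (self.y_obs < 0).any():
                raise ValueError("negative responses under the Poisson likelihood")
        else:
            self.y_obs = y[self.obs]
        self.X_obs = X[self.obs]
        self.X_mis = X[~self.obs]
        self.prior_sd = (self.spec.prior_sd if self.spec.prior_sd is not None
                         else self.spec.prior_scale_mult * max(self.y_obs.std(), 1e-12))

    # -- samplers --------------------------------------------------------
    def _run_normal_chain(self, rng, n_iter, start_shift):
        Xo, yo = self.X_obs, self.y_obs
        Xm = self.X_mis
        n_mis = Xm.shape[0]
        k = Xo.shape[1]
        tau2 = self.prior_sd**2
        a0, b0 = self.spec.sigma_prior_shape, self.spec.sigma_prior_rate
        beta = np.zeros(k) + start_shift
        fixed = self.spec.fixed_sigma2
        sigma2 = fixed if fixed is not None else max(yo.var(), 1e-6)
        n_all = len(self.y)
        XtX_o = Xo.T @ Xo
        Xty_o = Xo.T @ yo
        XtX_m = Xm.T @ Xm if n_mis else np.zeros((k, k))
        betas = np.empty((n_iter, k))
        sigmas = np.empty(n_iter)
        ymis_draws = np.empty((n_iter, n_mis))
        for it in range(n_iter):
            if n_mis:
                ymis = Xm @ beta + np.sqrt(sigma2) * rng.standard_normal(n_mis)
                Xty = Xty_o + Xm.T @ ymis
                XtX = XtX_o + XtX_m
            else:
                ymis = np.empty(0)
                Xty = Xty_o
                XtX = XtX_o
            V = np.linalg.inv(XtX / sigma2 + np.eye(k) / tau2)
            mean = V @ (Xty / sigma2)
            beta = mean + np.linalg.cholesky(V) @ rng.standard_normal(k)
            resid_o = yo - Xo @ beta
            rss = float(resid_o @ resid_o)
            if n_mis:
                rm = ymis - Xm @ beta
                rss += float(rm @ rm)
            if fixed is None:
                sigma2 = 1.0 / rng.gamma(a0 + n_all / 2.0, 1.0 / (b0 + rss / 2.0))
            betas[it] = beta
            sigmas[it] = np.sqrt(sigma2)
            if n_mis:
                ymis_draws[it] = ymis
        return betas, sigmas, ymis_draws, None

    def _run_poisson_chain(self, rng, n_iter, burn_in, start_shift, prop_scale):
        Xo, yo = self.X_obs, self.y_obs
        Xm = self.X_mis
        n_mis = Xm.shape[0]
        k = Xo.shape[1]
        tau2 = self.prior_sd**2

        def logpost(b):
            eta = np.clip(Xo @ b, -30, 30)
            return float(yo @ eta - np.exp(eta).sum() - 0.5 * b @ b / tau2)

        # start near the IRLS mode, shifted for over-dispersion
        beta = np.zeros(k)
        beta[0] = np.log(max(yo.mean(), 0.1))
        beta = beta + start_shift
        lp = logpost(beta)
        scale = prop_scale
        betas = np.empty((n_iter, k))
        ymis_draws = np.empty((n_iter, n_mis))
        accepted = 0
        tuned = 0
        for it in range(n_iter):
            prop = beta + scale * rng.standard_normal(k)
            lp_prop = logpost(prop)
            if np.log(rng.random()) < lp_prop - lp:
                beta, lp = prop, lp_prop
                accepted += 1
                tuned += 1
            if it < burn_in and (it + 1) % 100 == 0:  # adapt during burn-in only
                rate = tuned / 100.0
                tuned = 0
                if rate < 0.20:
                    scale *= 0.7
                elif rate > 0.40:
                    scale *= 1.4
            betas[it] = beta
            if n_mis:
                lam = np.exp(np.clip(Xm @ beta, -30, 30))
                ymis_draws[it] = rng.poisson(lam)
        return betas, None, ymis_draws, accepted / n_iter

    def _deviance(self, beta, sigma=None):
        if self.spec.likelihood == "normal-identity":
            resid = self.y_obs - self.X_obs @ beta
            n = len(self.y_obs)
            return float(n * np.log(2 * np.pi * sigma**2) + resid @ resid / sigma**2)
        eta = np.clip(self.X_obs @ beta, -30, 30)
        ll = float(self.y_obs @ eta - np.exp(eta).sum() -
                   special.gammaln(self.y_obs + 1).sum())
        return -2.0 * ll

    def fit(self, mcmc: McmcConfig | None = None,
            keep_imputations: bool = False) -> PosteriorSummary:
        mcmc = mcmc or McmcConfig()
        mcmc.validate()
        rng = np.random.default_rng(mcmc.seed)
        k = self.X.shape[1]
        chains_beta, chains_sigma, chains_ymis = [], [], []
        acc = []
        for c in range(mcmc.n_chains):
            # over-dispersed starts: +/- 2 prior SDs (scaled down to stay stable)
            shift = (2.0 * self.prior_sd / 10.0) * (1 if c % 2 == 0 else -1)
            crng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            if self.spec.likelihood == "normal-identity":
                b, s, ym, a = self._run_normal_chain(crng, mcmc.n_iter, shift)
            else:
                b, s, ym, a = self._run_poisson_chain(
                    crng, mcmc.n_iter, mcmc.burn_in, shift / max(self.prior_sd, 1.0),
                    mcmc.proposal_scale)
            sl = slice(mcmc.burn_in, None, mcmc.thin)
            chains_beta.append(b[sl])
            chains_sigma.append(s[sl] if s is not None else None)
            chains_ymis.append(ym[sl])
            if a is not None:
                acc.append(a)
        B = np.stack(chains_beta)  # (chains, draws, k)
        mean = B.reshape(-1, k).mean(axis=0)
        sd = B.reshape(-1, k).std(axis=0, ddof=1)
        ci_low = np.percentile(B.reshape(-1, k), 2.5, axis=0)
        ci_high = np.percentile(B.reshape(-1, k), 97.5, axis=0)
        if mcmc.n_chains >= 2:
            rhat = np.array([gelman_rubin(B[:, :, j]) for j in range(k)])
        else:
            rhat = np.full(k, np.nan)
        ess = np.array([effective_sample_size(B[:, :, j]) for j in range(k)])
        z = mean / np.where(sd > 0, sd, np.inf)
        pvals = 2.0 * stats.norm.sf(np.abs(z))

        # DIC over a thinned subsample of retained draws
        flatB = B.reshape(-1, k)
        if chains_sigma[0] is not None:
            flatS = np.concatenate(chains_sigma)
            sub = np.linspace(0, len(flatB) - 1, min(2000, len(flatB))).astype(int)
            dev = np.array([self._deviance(flatB[i], flatS[i]) for i in sub])
            dev_at_mean = self._deviance(mean, float(flatS.mean()))
        else:
            sub = np.linspace(0, len(flatB) - 1, min(2000, len(flatB))).astype(int)
            dev = np.array([self._deviance(flatB[i]) for i in sub])
            dev_at_mean = self._deviance(mean)
        dic_res = dic(dev, dev_at_mean)

        converged = bool(np.all(np.isnan(rhat)) or np.nanmax(rhat) <= 1.1)
        if not converged:
            warnings.warn(f"R-hat above 1.1 (max {np.nanmax(rhat):.3f}); "
                          "treat results as non-converged")
        acceptance = float(np.mean(acc)) if acc else None
        if acceptance is not None and not 0.05 <= acceptance <= 0.8:
            warnings.warn(f"Metropolis acceptance {acceptance:.2f} outside [0.05, 0.8]")
        imput = np.concatenate(chains_ymis) if keep_imputations else None
        return PosteriorSummary(
            list(self.terms), mean, sd, ci_low, ci_high, rhat, ess, pvals,
            dic_res, converged, acceptance, draws=B,
            sigma_draws=(np.concatenate(chains_sigma)
                         if chains_sigma[0] is not None else None),
            imputed_draws=imput, n_missing=int((~self.obs).sum()),
        )


def fit_bayes(table, response: str, covariates=("arm",),
              spec: ModelSpec | None = None,
              mcmc: McmcConfig | None = None, **kw) -> PosteriorSummary:
    """Functional facade over :class:`BayesGLM`."""
    return BayesGLM(table, response, covariates, spec).fit(mcmc, **kw)
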