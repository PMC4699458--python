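"""Maximum likelihood for the incomplete multivariate normal via EM.

This is the computational engine shared by the MCAR test and by
bootstrap-EM multiple imputation.  Rows are grouped by missingness
pattern; the E-step fills each pattern's missing block through Gaussian
conditioning on its observed block, the M-step recomputes the mean and
(denominator ``n``) covariance from the completed sufficient statistics.
The observed-data log-likelihood is monitored and must be non-decreasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

_LOG2PI = np.log(2.0 * np.pi)
_RIDGE = 1e-8


@dataclass
class MvnParams:
    """Mean vector, covariance matrix and fit diagnostics of an EM run."""

    mean: np.ndarray
    cov: np.ndarray
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = False
    loglik_path: list = field(default_factory=list, repr=False)
    ridged: bool = False

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean length")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() < -1e-10:
            raise ValueError("covariance is not (numerically) PSD")


@dataclass
class ConditionalGaussian:
    """Conditional distribution of a missing block given observed values."""

    mean: np.ndarray
    cov: np.ndarray

    @property
    def dim(self):
        return self.mean.size


def conditional_dist(params: MvnParams, observed_idx, observed_values) -> ConditionalGaussian:
    """N(mu_m + S_mo S_oo^-1 (y_o - mu_o),  S_mm - S_mo S_oo^-1 S_om).

    ``observed_idx`` indexes the observed variables; the conditional is over
    the complementary (missing) set, empty if everything is observed.
    """
    obs = np.asarray(observed_idx, int)
    if obs.size == 0:
        raise ValueError("observed_idx must be non-empty")
    p = params.mean.size
    mis = np.setdiff1d(np.arange(p), obs)
    y = np.asarray(observed_values, float)
    Soo = params.cov[np.ix_(obs, obs)]
    if mis.size == 0:
        return ConditionalGaussian(np.empty(0), np.empty((0, 0)))
    Smo = params.cov[np.ix_(mis, obs)]
    try:
        B = linalg.solve(Soo, Smo.T, assume_a="pos").T
    except linalg.LinAlgError:
        warnings.warn("singular observed-block covariance; using pseudo-inverse")
        B = Smo @ np.linalg.pinv(Soo)
    cmean = params.mean[mis] + B @ (y - params.mean[obs])
    ccov = params.cov[np.ix_(mis, mis)] - B @ Smo.T
    ccov = (ccov + ccov.T) / 2.0
    # clip tiny negative eigenvalues from the subtraction
    w, V = np.linalg.eigh(ccov)
    if w.min() < 0:
        ccov = (V * np.clip(w, 0.0, None)) @ V.T
    return ConditionalGaussian(cmean, ccov)


def _patterns(mask):
    """Group row indices by missingness pattern (key = mask bytes)."""
    groups = {}
    for i, row in enumerate(mask):
        groups.setdefault(row.tobytes(), []).append(i)
    return [(np.frombuffer(k, bool).copy(), np.asarray(idx)) for k, idx in groups.items()]


class MvnEM:
    """EM model for an incomplete multivariate normal sample.

    Parameters
    ----------
    data : (n, p) array
        Numeric matrix with NaN marking missing cells.  Every column must
        be observed at least twice; rows with no observed cell are dropped
        from estimation with a warning.
    """

    def __init__(self, data):
        data = np.asarray(data, float)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D matrix")
        mask = np.isnan(data)
        n_obs_col = (~mask).sum(axis=0)
        if (n_obs_col < 2).any():
            bad = np.nonzero(n_obs_col < 2)[0]
            raise ValueError(f"columns observed fewer than twice: {bad.tolist()}")
        empty = mask.all(axis=1)
        if empty.any():
            warnings.warn(f"dropping {int(empty.sum())} all-missing row(s) from estimation")
            data = data[~empty]
            mask = mask[~empty]
        self.data = data
        self.mask = mask
        self.n, self.p = data.shape
        self.pattern_groups = _patterns(mask)

    # -- likelihood ------------------------------------------------------
    def loglik(self, mean, cov) -> float:
        """Observed-data log-likelihood at (mean, cov)."""
        ll = 0.0
        for miss, idx in self.pattern_groups:
            obs = ~miss
            X = self.data[np.ix_(idx, np.nonzero(obs)[0])]
            mu = mean[obs]
            S = cov[np.ix_(obs, obs)]
            k, q = X.shape
            sign, logdet = np.linalg.slogdet(S)
            if sign <= 0:
                return -np.inf
            D = X - mu
            sol = linalg.solve(S, D.T, assume_a="pos")
            quad = np.einsum("ij,ji->", D, sol)
            ll += -0.5 * (k * q * _LOG2PI + k * logdet + quad)
        return float(ll)

    def _start(self):
        mean = np.nanmean(self.data, axis=0)
        var = np.nanvar(self.data, axis=0)
        var = np.where(var > 0, var, 1.0)
        return mean, np.diag(var)

    def fit(self, tol: float = 1e-6, max_iter: int = 500,
            start: MvnParams | None = None, prior_scale: float = 0.0) -> MvnParams:
        """Run EM to convergence (|Δ loglik| < tol) or ``max_iter``.

        ``prior_scale`` > 0 adds a diagonal ridge prior to the M-step
        covariance — Sigma = (SS + prior_scale * D0) / (n + prior_scale)
        with D0 the available-case variances — stabilising near-degenerate
        problems (p close to n) at the cost of shrinkage; the observed-data
        log-likelihood is then no longer guaranteed monotone and only the
        convergence criterion applies.
        """
        if start is not None:
            mean, cov = start.mean.copy(), start.cov.copy()
        else:
            mean, cov = self._start()
        D0 = np.diag(np.diag(cov if start is None else self._start()[1]))
        ridged = False
        path = []
        ll_old = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            S1 = np.zeros(self.p)
            S2 = np.zeros((self.p, self.p))
            for miss, idx in self.pattern_groups:
                X = self.data[idx]
                if not miss.any():
                    S1 += X.sum(axis=0)
                    S2 += X.T @ X
                    continue
                obs = np.nonzero(~miss)[0]
                mis = np.nonzero(miss)[0]
                Xo = X[:, obs]
                Soo = cov[np.ix_(obs, obs)]
                Smo = cov[np.ix_(mis, obs)]
                try:
                    B = linalg.solve(Soo, Smo.T, assume_a="pos").T
                except linalg.LinAlgError:
                    B = Smo @ np.linalg.pinv(Soo)
                Xm = mean[mis] + (Xo - mean[obs]) @ B.T
                C = cov[np.ix_(mis, mis)] - B @ Smo.T
                Xfull = np.empty((len(idx), self.p))
                Xfull[:, obs] = Xo
                Xfull[:, mis] = Xm
                S1 += Xfull.sum(axis=0)
                S2 += Xfull.T @ Xfull
                S2[np.ix_(mis, mis)] += len(idx) * C
            mean = S1 / self.n
            if prior_scale > 0:
                SS = S2 - self.n * np.outer(mean, mean)
                cov = (SS + prior_scale * D0) / (self.n + prior_scale)
            else:
                cov = S2 / self.n - np.outer(mean, mean)
            cov = (cov + cov.T) / 2.0
            if np.linalg.eigvalsh(cov).min() < _RIDGE:
                cov = cov + _RIDGE * np.eye(self.p)
                ridged = True
            ll = self.loglik(mean, cov)
            path.append(ll)
            strict = prior_scale == 0.0 and not ridged
            if strict and np.isfinite(ll_old) and ll < ll_old - 1e-8 * max(1.0, abs(ll_old)):
                raise RuntimeError(
                    f"EM log-likelihood decreased at iteration {it}: {ll_old} -> {ll}"
                )
            if np.isfinite(ll_old) and abs(ll - ll_old) < tol:
                converged = True
                ll_old = ll
                break
            ll_old = ll
        if not converged:
            warnings.warn(f"EM did not converge in {max_iter} iterations")
        return MvnParams(mean, cov, loglik=float(ll_old), n_iter=it,
                         converged=converged, loglik_path=path, ridged=ridged)


def em_fit(data, tol: float = 1e-6, max_iter: int = 500,
           start: MvnParams | None = None) -> MvnParams:
    """Functional facade over :class:`MvnEM`."""
    return MvnEM(data).fit(tol=tol, max_iter=max_iter, start=start)


def disperse_check(data, k_starts: int = 5, inflation: float = 4.0,
                   tol: float = 1e-4, seed: int = 0) -> dict:
    """EM from over-dispersed starts; do all runs agree on the optimum?

    Starts perturb the complete/available-case moments, with the starting
    covariance inflated by ``inflation``.  ``agree`` is true when every
    final log-likelihood is within ``tol`` of the best and the maximum
    pairwise parameter distance is below ``tol`` on the parameter scale.
    """
    if k_starts < 2:
        raise ValueError("k_starts must be >= 2")
    model = MvnEM(data)
    rng = np.random.default_rng(seed)
    mean0, cov0 = model._start()
    scale = np.sqrt(np.diag(cov0))
    results = []
    for _ in range(k_starts):
        m = mean0 + rng.standard_normal(model.p) * scale * np.sqrt(inflation)
        c = cov0 * inflation
        results.append(model.fit(start=MvnParams(m, c)))
    lls = np.array([r.loglik for r in results])
    thetas = [np.concatenate([r.mean, r.cov[np.triu_indices(model.p)]]) for r in results]
    dmax = max(
        float(np.max(np.abs(thetas[i] - thetas[j])))
        for i in range(k_starts) for j in range(i + 1, k_starts)
    )
    param_scale = max(1.0, float(np.max(np.abs(thetas[0]))))
    agree = bool(lls.max() - lls.min() < max(tol, 1e-6 * abs(lls.max()))
                 and dmax < tol * param_scale)
    return {
        "logliks": lls.tolist(),
        "max_param_distance": dmax,
        "agree": agree,
        "fits": results,
    }
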