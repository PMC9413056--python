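"""Shared numerical machinery for normal-theory structural models.

Everything downstream (the memory decomposition, the saturated H1 models
behind chi-square fit statistics, and the latent growth block) reduces to
multivariate-normal likelihoods evaluated under arbitrary per-cell
missingness.  This module provides:

* :func:`mvn_loglik_missing` -- full-information ML log-likelihood, each row
  contributing the marginal density of its observed sub-vector;
* :func:`em_saturated` -- EM estimation of the unrestricted mean/covariance
  (the H1 model) under missingness;
* :func:`fit_indices` / :func:`srmr` -- the standard SEM fit statistics
  (chi-square, RMSEA with 90% CI, CFI, TLI, SRMR);
* :func:`observed_info_se` -- standard errors from a central-difference
  observed information matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MvnModel",
    "FitIndices",
    "EmResult",
    "SingularModelError",
    "UnidentifiableVariableError",
    "SaturatedModelError",
    "DegenerateScaleError",
    "mvn_loglik_missing",
    "em_saturated",
    "fit_indices",
    "srmr",
    "observed_info_se",
]

_LOG2PI = np.log(2.0 * np.pi)


class SingularModelError(ValueError):
    """A model-implied covariance sub-block is not positive definite."""


class UnidentifiableVariableError(ValueError):
    """A variable is never (or almost never) observed."""


class SaturatedModelError(ValueError):
    """Fit indices requested for a model with zero degrees of freedom."""


class DegenerateScaleError(ValueError):
    """A variable has zero variance where a scale is required."""


@dataclass(frozen=True)
class MvnModel:
    """Model-implied moments of a multivariate normal.

    Parameters
    ----------
    mean : (p,) array
        Model-implied means, in the units of the observed variables.
    cov : (p, p) array
        Model-implied covariance matrix; must be symmetric and positive
        semi-definite to tolerance 1e-10.
    labels : tuple of str
        Ordered variable names matching ``mean``/``cov``.
    """

    mean: np.ndarray
    cov: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        labels = tuple(self.labels)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        object.__setattr__(self, "labels", labels)
        p = len(labels)
        if mean.shape != (p,) or cov.shape != (p, p):
            raise ValueError(
                f"dimension mismatch: {p} labels, mean {mean.shape}, cov {cov.shape}"
            )
        if not np.allclose(cov, cov.T, atol=1e-8, rtol=1e-8):
            raise ValueError("covariance matrix is not symmetric")
        eigmin = float(np.linalg.eigvalsh((cov + cov.T) / 2.0).min()) if p else 0.0
        scale = max(1.0, float(np.abs(cov).max())) if p else 1.0
        if eigmin < -1e-10 * scale:
            raise ValueError(f"covariance not PSD (min eigenvalue {eigmin:g})")

    @property
    def nvar(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class FitIndices:
    """Standard SEM fit statistics for an H0 model against the saturated H1."""

    chisq: float
    df: int
    rmsea: float
    rmsea_ci90: tuple[float, float]
    cfi: float
    tli: float
    srmr: float | None
    n_used: int

    def __post_init__(self):
        if self.chisq < 0 or self.df < 0 or self.rmsea < 0:
            raise ValueError("chisq, df and rmsea must be nonnegative")
        lo, hi = self.rmsea_ci90
        if not (lo - 1e-12 <= self.rmsea <= hi + 1e-12):
            raise ValueError("rmsea outside its own 90% CI")


@dataclass
class EmResult:
    """Result of :func:`em_saturated`."""

    model: MvnModel
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: np.ndarray = field(repr=False, default=None)


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"v{j}" for j in range(arr.shape[1])]


def _pattern_groups(mask: np.ndarray):
    """Group row indices by observed-cell pattern (mask True = observed)."""
    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    for k in range(patterns.shape[0]):
        yield patterns[k].astype(bool), np.flatnonzero(inverse == k)


def mvn_loglik_missing(data, model: MvnModel) -> float:
    """Full-information log-likelihood of rows with per-cell missingness.

    Each row contributes the log-density of its observed sub-vector under
    the corresponding marginal normal; rows with no observed cells
    contribute exactly zero.
    """
    X, labels = _as_matrix(data)
    if X.shape[1] != model.nvar:
        raise ValueError("data/model dimension mismatch")
    mask = ~np.isnan(X)
    total = 0.0
    for obs, idx in _pattern_groups(mask):
        k = int(obs.sum())
        if k == 0:
            continue
        sub = X[np.ix_(idx, obs)]
        mu = model.mean[obs]
        sigma = model.cov[np.ix_(obs, obs)]
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            names = [model.labels[j] for j in np.flatnonzero(obs)]
            raise SingularModelError(
                "model covariance not positive definite on observed "
                f"sub-block {names}"
            ) from None
        dev = sub - mu
        sol = np.linalg.solve(chol, dev.T)
        quad = np.einsum("ij,ij->j", sol, sol)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        total += float(-0.5 * (k * _LOG2PI + logdet) * len(idx) - 0.5 * quad.sum())
    return total


def em_saturated(
    data,
    tol: float = 1e-8,
    max_iter: int = 500,
    labels: list[str] | None = None,
) -> EmResult:
    """ML mean/covariance of an unrestricted MVN under missing data, via EM.

    Uses the ML divisor ``n`` (not ``n-1``).  The log-likelihood is
    non-decreasing across iterations; convergence is declared when the
    change drops below ``tol`` (log-likelihood units).
    """
    X, default_labels = _as_matrix(data)
    labels = list(labels) if labels is not None else default_labels
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    mask = ~np.isnan(X)
    n_obs = mask.sum(axis=0)
    if np.any(n_obs < 2):
        bad = [labels[j] for j in np.flatnonzero(n_obs < 2)]
        raise UnidentifiableVariableError(
            f"variables observed fewer than 2 times: {bad}"
        )

    # Start from available-case moments.
    mu = np.nanmean(X, axis=0)
    Xc = np.where(mask, X, mu)
    sigma = np.cov(Xc, rowvar=False, bias=True) + 1e-6 * np.eye(p)
    if p == 1:
        sigma = sigma.reshape(1, 1)

    groups = list(_pattern_groups(mask))
    complete = bool(mask.all())
    lls = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: expected sufficient statistics per pattern.
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        ll = 0.0
        for obs, idx in groups:
            miss = ~obs
            ni = len(idx)
            xo = X[np.ix_(idx, obs)]
            k = int(obs.sum())
            if k == 0:
                # nothing observed: conditional is the marginal
                s1 += ni * mu
                s2 += ni * (sigma + np.outer(mu, mu))
                continue
            Soo = sigma[np.ix_(obs, obs)]
            chol = np.linalg.cholesky(Soo + 1e-12 * np.eye(k))
            dev = xo - mu[obs]
            sol = np.linalg.solve(chol, dev.T)
            quad = np.einsum("ij,ij->j", sol, sol)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            ll += float(-0.5 * (k * _LOG2PI + logdet) * ni - 0.5 * quad.sum())
            full = np.empty((ni, p))
            full[:, obs] = xo
            if miss.any():
                Smo = sigma[np.ix_(miss, obs)]
                # regression of missing on observed
                B = np.linalg.solve(Soo, Smo.T).T  # (m, k)
                cond_mean = mu[miss] + dev @ B.T
                full[:, miss] = cond_mean
                cond_cov = sigma[np.ix_(miss, miss)] - B @ Smo.T
                add = np.zeros((p, p))
                add[np.ix_(miss, miss)] = cond_cov * ni
                s2 += add
            s1 += full.sum(axis=0)
            s2 += full.T @ full
        lls.append(ll)
        # M-step
        mu = s1 / n
        sigma = s2 / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2.0
        if complete or abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
    if not converged:
        warnings.warn(
            f"em_saturated: not converged after {max_iter} iterations",
            RuntimeWarning,
        )
    model = MvnModel(mean=mu, cov=sigma, labels=tuple(labels))
    try:
        final_ll = mvn_loglik_missing(X, model)
    except SingularModelError:
        # degenerate (perfectly collinear) data: report the likelihood at a
        # minimally ridged covariance; the moments themselves are exact
        scale = max(float(np.abs(sigma).max()), 1.0)
        ridged = MvnModel(mean=mu, cov=sigma + 1e-10 * scale * np.eye(p),
                          labels=tuple(labels))
        final_ll = mvn_loglik_missing(X, ridged)
    lls.append(final_ll)
    return EmResult(
        model=model,
        loglik=final_ll,
        n_iter=it,
        converged=converged,
        loglik_path=np.asarray(lls),
    )


def _rmsea_ci(chisq: float, df: int, n: int, denom: float, level: float = 0.90):
    """90% CI for RMSEA by inverting the noncentral chi-square."""
    alpha = (1.0 - level) / 2.0

    def upper_tail_root(target):
        # find lambda with ncx2.cdf(chisq, df, lam) = target
        def f(lam):
            return stats.ncx2.cdf(chisq, df, lam) - target

        if f(0.0) < 0:
            return 0.0
        hi = max(chisq, 1.0)
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e8:
                return hi
        return optimize.brentq(f, 0.0, hi, xtol=1e-10)

    if chisq <= stats.chi2.ppf(1.0 - alpha, df):
        lam_lo = 0.0
    else:
        lam_lo = upper_tail_root(1.0 - alpha)
    if chisq <= stats.chi2.ppf(alpha, df):
        lam_hi = 0.0
    else:
        lam_hi = upper_tail_root(alpha)
    lo = np.sqrt(max(lam_lo, 0.0) / denom)
    hi = np.sqrt(max(lam_hi, 0.0) / denom)
    return float(lo), float(hi)


def fit_indices(
    loglik_h0: float,
    nparam_h0: int,
    loglik_h1: float,
    nparam_h1: int,
    loglik_base: float,
    nparam_base: int,
    n: int,
    rmsea_denominator: str = "n-1",
    srmr_value: float | None = None,
) -> FitIndices:
    """Chi-square based fit indices for H0 against the saturated H1.

    ``rmsea_denominator`` selects the Steiger ``n-1`` convention (default)
    or the ``n`` convention used by some software.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if loglik_h1 < loglik_h0 - 1e-6:
        raise ValueError("H1 log-likelihood below H0: models are mis-ordered")
    df = int(nparam_h1) - int(nparam_h0)
    if df <= 0:
        raise SaturatedModelError("H0 is saturated (df = 0): indices undefined")
    chisq = max(2.0 * (loglik_h1 - loglik_h0), 0.0)
    df_base = int(nparam_h1) - int(nparam_base)
    chisq_base = max(2.0 * (loglik_h1 - loglik_base), 0.0)

    denom = df * ((n - 1) if rmsea_denominator == "n-1" else n)
    rmsea = float(np.sqrt(max(chisq - df, 0.0) / denom))
    if chisq <= df:
        ci = (0.0, 0.0) if rmsea == 0.0 else (0.0, rmsea)
        ci = _rmsea_ci(chisq, df, n, denom)
        ci = (min(ci[0], rmsea), max(ci[1], rmsea))
    else:
        ci = _rmsea_ci(chisq, df, n, denom)
        ci = (min(ci[0], rmsea), max(ci[1], rmsea))

    denom_cfi = max(chisq_base - df_base, chisq - df, 0.0)
    cfi = 1.0 if denom_cfi == 0.0 else 1.0 - max(chisq - df, 0.0) / denom_cfi
    cfi = float(np.clip(cfi, 0.0, 1.0))
    if df_base > 0 and chisq_base > 0:
        ratio_base = chisq_base / df_base
        ratio = chisq / df
        tli = (ratio_base - ratio) / (ratio_base - 1.0) if ratio_base != 1.0 else 1.0
    else:
        tli = 1.0
    return FitIndices(
        chisq=float(chisq),
        df=df,
        rmsea=rmsea,
        rmsea_ci90=ci,
        cfi=cfi,
        tli=float(tli),
        srmr=srmr_value,
        n_used=int(n),
    )


def srmr(observed: MvnModel, implied: MvnModel, include_means: bool = False) -> float:
    """Standardized root mean square residual between two moment structures.

    Computed over the unique covariance entries (lower triangle including
    the diagonal), residuals standardized by the observed standard
    deviations; mean residuals excluded unless ``include_means``.
    """
    if observed.labels != implied.labels:
        raise ValueError("observed and implied models must share labels/order")
    sd = np.sqrt(np.diag(observed.cov))
    if np.any(sd <= 0):
        bad = [observed.labels[j] for j in np.flatnonzero(sd <= 0)]
        raise DegenerateScaleError(f"zero observed variance: {bad}")
    scale = np.outer(sd, sd)
    resid = (observed.cov - implied.cov) / scale
    tril = np.tril_indices(observed.nvar)
    vals = resid[tril] ** 2
    if include_means:
        mean_resid = (observed.mean - implied.mean) / sd
        vals = np.concatenate([vals, mean_resid**2])
    return float(np.sqrt(vals.mean()))


def observed_info_se(
    loglik_fn,
    theta_hat: np.ndarray,
    step: float = 1e-5,
) -> np.ndarray:
    """Standard errors from the central-difference observed information.

    Returns NaN for coordinates where the information matrix is singular
    (flat directions) instead of failing; warns if the Hessian has positive
    diagonal curvature at the claimed maximum.
    """
    theta = np.asarray(theta_hat, dtype=float)
    k = theta.size
    h = step * np.maximum(1.0, np.abs(theta))
    H = np.empty((k, k))
    f0 = loglik_fn(theta)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                tp = theta.copy()
                tp[i] += h[i]
                tm = theta.copy()
                tm[i] -= h[i]
                H[i, i] = (loglik_fn(tp) - 2.0 * f0 + loglik_fn(tm)) / h[i] ** 2
            else:
                tpp = theta.copy()
                tpp[[i, j]] += [h[i], h[j]]
                tpm = theta.copy()
                tpm[i] += h[i]
                tpm[j] -= h[j]
                tmp = theta.copy()
                tmp[i] -= h[i]
                tmp[j] += h[j]
                tmm = theta.copy()
                tmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (
                    loglik_fn(tpp) - loglik_fn(tpm) - loglik_fn(tmp) + loglik_fn(tmm)
                ) / (4.0 * h[i] * h[j])
    if np.any(np.diag(H) > 1e-8 * np.maximum(1.0, np.abs(np.diag(H)).max())):
        warnings.warn(
            "observed_info_se: positive curvature at claimed maximum",
            RuntimeWarning,
        )
    info = -H
    se = np.full(k, np.nan)
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        ok = diag > 0
        se[ok] = np.sqrt(diag[ok])
        if not np.all(np.isfinite(se[ok])):
            raise np.linalg.LinAlgError
        if np.linalg.cond(info) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        # flag flat directions, salvage the rest via eigendecomposition
        evals, evecs = np.linalg.eigh(info)
        tol = max(np.abs(evals).max(), 1.0) * 1e-10
        se[:] = np.nan
        good = evals > tol
        if good.any():
            cov = (evecs[:, good] / evals[good]) @ evecs[:, good].T
            diag = np.diag(cov)
            # coordinates dominated by a null direction stay NaN
            null_load = (evecs[:, ~good] ** 2).sum(axis=1) if (~good).any() else np.zeros(k)
            for i in range(k):
                if null_load[i] < 1e-6 and diag[i] > 0:
                    se[i] = np.sqrt(diag[i])
    return se
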