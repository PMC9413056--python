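"""Maximum-likelihood decomposition of baseline memory into explained and
residual (reserve) components.

The model regresses the memory composite on demographic and brain-integrity
predictors, splits the residual variance into a latent reserve component
(``MEMR``, variance ``psi``) plus a *fixed* measurement-error variance
``theta`` (default 0.161, supplied as prior knowledge, not estimated), and
constrains the latent residual to be uncorrelated with every predictor.

Estimation goes through the saturated joint moments of (predictors, memory)
obtained by EM under missingness (full-information ML); the regression
coefficients and variance split are then exact algebraic functions of those
moments.  On complete data this reproduces OLS coefficients exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .likelihood import (
    DegenerateScaleError,
    EmResult,
    FitIndices,
    MvnModel,
    em_saturated,
    fit_indices,
    mvn_loglik_missing,
    observed_info_se,
    srmr,
)

__all__ = [
    "DecompositionSpec",
    "DecompositionFit",
    "CollinearityError",
    "fit_decomposition_ml",
    "factor_scores",
    "standardize_estimates",
]

DEFAULT_PREDICTORS = (
    "age_c", "sex", "educ_c", "apoe4",
    "hcv_adj", "wbv_adj", "logwmh",
    "abeta_ratio", "ptau_t0", "fdg_t0",
)


class CollinearityError(ValueError):
    """Predictor covariance matrix is numerically singular."""


@dataclass
class DecompositionSpec:
    """Configuration of the memory-decomposition model.

    ``zero_cov_constraints`` lists predictor pairs whose covariance is fixed
    to zero (these contribute the model's degrees of freedom); the latent
    residual's covariances with every predictor are always zero and are not
    configurable.  ``drop`` removes predictors (e.g., race/ethnicity) for
    parsimony.
    """

    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    mem_col: str = "mem_t0"
    fixed_error_variance: float = 0.161
    zero_cov_constraints: tuple[tuple[str, str], ...] = ()
    drop: tuple[str, ...] = ()

    def __post_init__(self):
        if self.fixed_error_variance <= 0:
            raise ValueError("fixed_error_variance must be > 0")
        self.predictors = tuple(p for p in self.predictors if p not in set(self.drop))
        for a, b in self.zero_cov_constraints:
            if a not in self.predictors or b not in self.predictors:
                raise ValueError(f"constraint ({a},{b}) names unknown predictor")
            if a == b:
                raise ValueError("cannot constrain a variance to zero")


@dataclass
class DecompositionFit:
    """Fitted decomposition model."""

    beta: pd.Series
    intercept: float
    psi_hat: float
    theta: float
    ses: pd.Series                      # SEs for intercept, betas, psi
    loglik: float
    fit: FitIndices | None
    n_used: int
    boundary: bool
    predictor_mean: np.ndarray
    predictor_cov: np.ndarray
    mem_sd: float
    labels: tuple[str, ...]
    em: EmResult = field(repr=False, default=None)

    @property
    def total_residual_variance(self) -> float:
        return self.psi_hat + self.theta


def _extract_conditional(model: MvnModel, p: int):
    """Split joint (predictors, memory) moments into regression form."""
    mu_x = model.mean[:p]
    mu_y = model.mean[p]
    sxx = model.cov[:p, :p]
    sxy = model.cov[:p, p]
    syy = model.cov[p, p]
    return mu_x, mu_y, sxx, sxy, syy


def _check_collinearity(sxx: np.ndarray, labels):
    cond = np.linalg.cond(sxx)
    if cond > 1e10:
        evals, evecs = np.linalg.eigh(sxx)
        v = np.abs(evecs[:, 0])
        dep = [labels[j] for j in np.flatnonzero(v > 0.1 * v.max())]
        raise CollinearityError(
            f"predictors numerically collinear (cond={cond:.3g}); dependent set {dep}"
        )


def _constrained_saturated(data: np.ndarray, labels, constraints, start: MvnModel):
    """ML saturated moments with selected covariances fixed to zero.

    No closed form exists; the free mean/covariance entries are maximized
    numerically against the missing-data likelihood, starting from the
    unconstrained EM solution with the constrained entries zeroed.
    """
    p = len(labels)
    idx = {name: j for j, name in enumerate(labels)}
    fixed = {tuple(sorted((idx[a], idx[b]))) for a, b in constraints}
    tril = [(i, j) for i in range(p) for j in range(i + 1)
            if tuple(sorted((i, j))) not in fixed]

    cov0 = start.cov.copy()
    for (i, j) in fixed:
        cov0[i, j] = cov0[j, i] = 0.0

    def unpack(theta):
        mean = theta[:p]
        cov = np.zeros((p, p))
        for k, (i, j) in enumerate(tril):
            cov[i, j] = cov[j, i] = theta[p + k]
        return mean, cov

    def negll(theta):
        mean, cov = unpack(theta)
        try:
            np.linalg.cholesky(cov + 1e-12 * np.eye(p))
        except np.linalg.LinAlgError:
            return 1e12
        model = MvnModel(mean=mean, cov=cov, labels=tuple(labels))
        try:
            return -mvn_loglik_missing(data, model)
        except Exception:
            return 1e12

    theta0 = np.concatenate([start.mean, [cov0[i, j] for (i, j) in tril]])
    res = optimize.minimize(negll, theta0, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-12})
    mean, cov = unpack(res.x)
    model = MvnModel(mean=mean, cov=(cov + cov.T) / 2.0, labels=tuple(labels))
    return model, -res.fun


def _independence_loglik(data: np.ndarray) -> tuple[float, int]:
    """Baseline (independence) model: per-variable ML mean/variance."""
    ll = 0.0
    p = data.shape[1]
    for j in range(p):
        col = data[:, j]
        col = col[~np.isnan(col)]
        m, v = col.mean(), col.var()
        ll += float(-0.5 * len(col) * (np.log(2 * np.pi * v) + 1.0))
    return ll, 2 * p


def fit_decomposition_ml(table: pd.DataFrame, spec: DecompositionSpec) -> DecompositionFit:
    """Fit the decomposition model by full-information maximum likelihood."""
    cols = list(spec.predictors) + [spec.mem_col]
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise KeyError(f"table lacks required columns {missing_cols}")
    data = table[cols].to_numpy(dtype=float)
    n = int((~np.isnan(data).all(axis=1)).sum())
    p = len(spec.predictors)
    theta = spec.fixed_error_variance

    em = em_saturated(data, labels=cols)
    h1_model, h1_ll = em.model, em.loglik

    if spec.zero_cov_constraints:
        h0_model, h0_ll = _constrained_saturated(
            data, cols, spec.zero_cov_constraints, h1_model
        )
    else:
        h0_model, h0_ll = h1_model, h1_ll

    mu_x, mu_y, sxx, sxy, syy = _extract_conditional(h0_model, p)
    _check_collinearity(sxx, spec.predictors)
    beta = np.linalg.solve(sxx, sxy)
    resid_var = float(syy - beta @ sxy)
    boundary = resid_var < theta
    if boundary:
        warnings.warn(
            f"residual variance {resid_var:.4f} below fixed error variance "
            f"{theta}; psi clipped to 0 (boundary solution)",
            RuntimeWarning,
        )
    psi_hat = max(resid_var - theta, 0.0)
    intercept = float(mu_y - beta @ mu_x)

    # profile observed-information SEs for (intercept, beta, psi), holding
    # the predictor moments at their ML values
    def profile_ll(params):
        b0 = params[0]
        b = params[1 : p + 1]
        psi = params[p + 1]
        if psi + theta <= 1e-10:
            return -1e12
        mean = np.concatenate([mu_x, [b0 + b @ mu_x]])
        cov = np.zeros((p + 1, p + 1))
        cov[:p, :p] = sxx
        cov[:p, p] = cov[p, :p] = sxx @ b
        cov[p, p] = b @ sxx @ b + psi + theta
        try:
            return mvn_loglik_missing(data, MvnModel(mean, cov, tuple(cols)))
        except Exception:
            return -1e12

    theta_hat = np.concatenate([[intercept], beta, [psi_hat]])
    if boundary:
        se = np.full(p + 2, np.nan)
        se[:-1] = observed_info_se(
            lambda t: profile_ll(np.concatenate([t, [psi_hat]])), theta_hat[:-1]
        )
    else:
        se = observed_info_se(profile_ll, theta_hat)
    se_index = ["intercept"] + list(spec.predictors) + ["psi"]

    fit_idx = None
    if spec.zero_cov_constraints:
        df_constraints = len(spec.zero_cov_constraints)
        nparam_h1 = (p + 1) + (p + 1) * (p + 2) // 2
        nparam_h0 = nparam_h1 - df_constraints
        ll_base, nparam_base = _independence_loglik(data)
        srmr_val = srmr(h1_model, h0_model)
        fit_idx = fit_indices(
            loglik_h0=h0_ll, nparam_h0=nparam_h0,
            loglik_h1=h1_ll, nparam_h1=nparam_h1,
            loglik_base=ll_base, nparam_base=nparam_base,
            n=n, srmr_value=srmr_val,
        )

    return DecompositionFit(
        beta=pd.Series(beta, index=list(spec.predictors)),
        intercept=intercept,
        psi_hat=float(psi_hat),
        theta=float(theta),
        ses=pd.Series(se, index=se_index),
        loglik=float(h0_ll),
        fit=fit_idx,
        n_used=n,
        boundary=bool(boundary),
        predictor_mean=mu_x,
        predictor_cov=sxx,
        mem_sd=float(np.sqrt(syy)),
        labels=tuple(cols),
        em=em,
    )


def factor_scores(fit: DecompositionFit, table: pd.DataFrame) -> pd.Series:
    """Regression-method reserve scores, one per subject.

    For complete predictor rows the score is the shrunken raw residual
    ``psi/(psi+theta) * (mem - intercept - x @ beta)``; rows with missing
    predictors replace the linear predictor by its conditional expectation
    given the observed predictors under the saturated moments.  Missing
    memory yields a missing score.
    """
    p = len(fit.beta)
    X = table[list(fit.beta.index)].to_numpy(dtype=float)
    y = table[fit.labels[-1]].to_numpy(dtype=float)
    lam = fit.psi_hat / (fit.psi_hat + fit.theta)
    mu_x, sxx = fit.predictor_mean, fit.predictor_cov
    beta = fit.beta.to_numpy()

    lin = np.full(len(table), np.nan)
    mask = ~np.isnan(X)
    for obs_pattern in np.unique(mask, axis=0):
        rows = np.flatnonzero((mask == obs_pattern).all(axis=1))
        obs = obs_pattern.astype(bool)
        Xr = X[rows]
        if obs.all():
            lin[rows] = Xr @ beta
            continue
        miss = ~obs
        xe = np.empty((len(rows), p))
        xe[:, obs] = Xr[:, obs]
        if obs.any():
            Soo = sxx[np.ix_(obs, obs)]
            Smo = sxx[np.ix_(miss, obs)]
            Bm = np.linalg.solve(Soo, Smo.T).T
            xe[:, miss] = mu_x[miss] + (Xr[:, obs] - mu_x[obs]) @ Bm.T
        else:
            xe[:, miss] = mu_x[miss]
        lin[rows] = xe @ beta
    score = lam * (y - fit.intercept - lin)
    return pd.Series(score, index=table.index, name="memr_score")


def standardize_estimates(fit: DecompositionFit) -> pd.Series:
    """Standardized coefficients ``beta_j * SD(x_j) / SD(memory)``."""
    sd_x = np.sqrt(np.diag(fit.predictor_cov))
    if np.any(sd_x <= 0) or fit.mem_sd <= 0:
        bad = [fit.beta.index[j] for j in np.flatnonzero(sd_x <= 0)]
        raise DegenerateScaleError(f"zero-variance predictor(s): {bad}")
    return fit.beta * sd_x / fit.mem_sd
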