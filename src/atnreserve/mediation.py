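"""Moderated sequential mediation with a latent-growth executive-function
outcome.

The structural model follows the conditional-process tradition (all paths
of a two-mediator serial mediation moderated by a single moderator W):

* tau equation:      M1 = tau_const + a1*X + g_tau*W + a1w*X*W + e1
* FDG equation:      M2 = fdg_const + a2*X + d21*M1 + g_fdg*W
                          + a2w*X*W + d21w*M1*W + e2
* growth equations:  I  = intercept_const + c_I*X + b1_I*M1 + b2_I*M2
                          + g_I*W + cw_I*X*W + b1w_I*M1*W + b2w_I*M2*W
                          + covariates + zeta_I            (same form for S)
* measurement:       EF_t = I + lambda_t * S + eps_t,  lambda_t = t - 3

X is the amyloid ratio, M1 plasma p-tau181, M2 FDG SUVR, W the residual
reserve index; the EF intercept is centred at the third annual visit and
the slope is per year.  Estimation is maximum likelihood: the mediator
equations are linear regressions; the growth block maximizes the marginal
normal likelihood of each subject's *observed* EF values (random intercept
and slope integrated out), so longitudinal dropout is handled by
full-information ML.  Product terms are treated as fixed regressors.

The growth likelihood is profiled: for fixed variance parameters
(log-Cholesky of the growth-factor residual covariance plus log residual
variance) the fixed effects have a closed-form GLS solution, leaving a
four-dimensional smooth optimization with an analytic gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .cohort import EF_COLUMNS
from .likelihood import (
    FitIndices,
    MvnModel,
    em_saturated,
    fit_indices,
    mvn_loglik_missing,
    srmr,
)

__all__ = [
    "MediationSpec",
    "MediationDataset",
    "MediationFit",
    "build_design",
    "fit_growth_mediation",
    "model_fit_indices",
    "predict_trajectories",
    "mediator_designs",
]

ALL_INTERACTIONS = ("a1w", "a2w", "d21w", "b1w", "b2w", "cw")


@dataclass
class MediationSpec:
    """Variable roles and structure of the moderated mediation model."""

    x_col: str = "abeta_ratio"
    w_col: str = "memr"
    m1_col: str = "ptau_t1"
    m2_col: str = "fdg_t2"
    ef_cols: tuple[str, ...] = EF_COLUMNS
    covariates: tuple[str, ...] = ("age_c", "sex", "educ_c")
    interactions: tuple[str, ...] = ALL_INTERACTIONS
    slope_loadings: tuple[float, ...] = tuple(float(t - 3) for t in range(8))
    ef_residual: str = "shared"          # "shared" or "per_time"
    covariates_on_mediators: bool = False

    def __post_init__(self):
        if len(self.slope_loadings) != len(self.ef_cols):
            raise ValueError("slope_loadings must match ef_cols length")
        unknown = set(self.interactions) - set(ALL_INTERACTIONS)
        if unknown:
            raise ValueError(f"unknown interaction terms {sorted(unknown)}")
        if self.ef_residual not in ("shared", "per_time"):
            raise ValueError("ef_residual must be 'shared' or 'per_time'")

    def cov_name(self, col: str, outcome: str) -> str:
        return f"cov_{col.removesuffix('_c')}_{outcome}"


@dataclass
class MediationDataset:
    """Analysis arrays produced by :func:`build_design`."""

    x: np.ndarray
    w: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    xw: np.ndarray
    m1w: np.ndarray
    m2w: np.ndarray
    cov: np.ndarray                    # (n, n_cov)
    ef: np.ndarray                     # (n, T) with NaN for missing
    spec: MediationSpec
    index: np.ndarray = None

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def covariate_means(self) -> np.ndarray:
        return self.cov.mean(axis=0) if self.cov.size else np.zeros(0)

    def take(self, idx: np.ndarray) -> "MediationDataset":
        """Row-resampled copy (used by the case bootstrap)."""
        return MediationDataset(
            x=self.x[idx], w=self.w[idx], m1=self.m1[idx], m2=self.m2[idx],
            xw=self.xw[idx], m1w=self.m1w[idx], m2w=self.m2w[idx],
            cov=self.cov[idx], ef=self.ef[idx], spec=self.spec,
            index=None,
        )


def build_design(table: pd.DataFrame, spec: MediationSpec) -> MediationDataset:
    """Construct product columns and restrict to analyzable subjects.

    Subjects must have complete X, W, M1, M2 and covariates (the analysis
    subsample with full biomarker coverage); EF columns keep their
    missingness for FIML handling in the growth block.
    """
    needed = [spec.x_col, spec.w_col, spec.m1_col, spec.m2_col, *spec.covariates]
    missing = [c for c in needed + list(spec.ef_cols) if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks columns {missing}")
    base = table[needed].to_numpy(dtype=float)
    ok = ~np.isnan(base).any(axis=1)
    if not ok.any():
        raise ValueError("no subjects with complete X, W, M1, M2 and covariates")
    sub = table.loc[ok]
    x = sub[spec.x_col].to_numpy(dtype=float)
    w = sub[spec.w_col].to_numpy(dtype=float)
    m1 = sub[spec.m1_col].to_numpy(dtype=float)
    m2 = sub[spec.m2_col].to_numpy(dtype=float)
    cov = sub[list(spec.covariates)].to_numpy(dtype=float) if spec.covariates \
        else np.zeros((len(sub), 0))
    ef = sub[list(spec.ef_cols)].to_numpy(dtype=float)
    return MediationDataset(
        x=x, w=w, m1=m1, m2=m2, xw=x * w, m1w=m1 * w, m2w=m2 * w,
        cov=cov, ef=ef, spec=spec, index=sub.index.to_numpy(),
    )


@dataclass
class MediationFit:
    """All structural coefficients, variance components and block fits."""

    coefficients: pd.Series
    ses: pd.Series
    psi_eta: np.ndarray
    theta_ef: np.ndarray                 # (1,) shared or (T,) per time
    logliks: dict[str, float]
    n_used: int
    converged: bool
    phi: np.ndarray                      # variance parameters (internal scale)
    nparams: dict[str, int]
    fit: FitIndices | None = None
    x_sd: float = 1.0
    w_sd: float = 1.0
    covariate_means: np.ndarray = field(default_factory=lambda: np.zeros(0))
    covariate_names: tuple[str, ...] = ()

    def coef(self, name: str) -> float:
        return float(self.coefficients.get(name, 0.0))


def _ols_block(yv: np.ndarray, cols: list[np.ndarray], names: list[str]):
    """ML linear regression block: coefficients, ML SEs, loglik."""
    X = np.column_stack(cols)
    n = len(yv)
    coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    s2 = float(resid @ resid) / n
    ll = -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * s2)
    return dict(zip(names, coef)), dict(zip(names, se)), float(ll), s2, len(names) + 1


def _growth_patterns(u: np.ndarray, ef: np.ndarray, loadings: np.ndarray):
    """Group subjects by observed-EF pattern; precompute per-pattern blocks."""
    mask = ~np.isnan(ef)
    patterns = []
    for pat in np.unique(mask, axis=0):
        rows = np.flatnonzero((mask == pat).all(axis=1))
        obs = pat.astype(bool)
        k = int(obs.sum())
        if k == 0:
            continue
        Z = np.column_stack([np.ones(k), loadings[obs]])
        U = u[rows]
        Y = ef[np.ix_(rows, obs)]
        patterns.append({
            "Z": Z, "U": U, "Y": Y, "Suu": U.T @ U,
            "n": len(rows), "k": k, "times": np.flatnonzero(obs),
            "rows": rows,
        })
    return patterns


def _phi_to_var(phi: np.ndarray, n_times: int, shared: bool):
    L = np.array([[np.exp(phi[0]), 0.0], [phi[1], np.exp(phi[2])]])
    psi = L @ L.T
    if shared:
        sig2 = np.full(n_times, np.exp(phi[3]))
    else:
        sig2 = np.exp(phi[3:3 + n_times])
    return L, psi, sig2


def _growth_negll(phi, patterns, p, n_times, shared, want_grad=True):
    """Profile -log-likelihood of the growth block and its gradient.

    Fixed effects gamma (length 2p: intercept-equation then slope-equation
    coefficients) are concentrated out by GLS.  Returns
    (nll, grad, gamma, normal_matrix).
    """
    L, psi, sig2 = _phi_to_var(phi, n_times, shared)
    P2 = 2 * p
    N = np.zeros((P2, P2))
    rhs = np.zeros(P2)
    yvy = 0.0
    logdet = 0.0
    const = 0.0
    cache = []
    for pat in patterns:
        Z, U, Y = pat["Z"], pat["U"], pat["Y"]
        k, npat = pat["k"], pat["n"]
        V = Z @ psi @ Z.T + np.diag(sig2[pat["times"]])
        cho = linalg.cho_factor(V, lower=True)
        Vinv = linalg.cho_solve(cho, np.eye(k))
        C = Z.T @ Vinv @ Z
        N += np.kron(C, pat["Suu"])
        Pzt = Z.T @ Vinv                       # 2 x k
        Q = Y @ Pzt.T                          # n_p x 2
        rhs[:p] += U.T @ Q[:, 0]
        rhs[p:] += U.T @ Q[:, 1]
        yvy += float(np.einsum("ij,jk,ik->", Y, Vinv, Y))
        logdet += npat * 2.0 * float(np.log(np.diag(cho[0])).sum())
        const += npat * k * np.log(2.0 * np.pi)
        cache.append((Z, U, Y, Vinv, pat))
    gamma = np.linalg.solve(N, rhs)
    m2ll = const + logdet + yvy - float(gamma @ rhs)
    nll = 0.5 * m2ll
    if not want_grad:
        return nll, None, gamma, N

    # dPsi per log-Cholesky coordinate
    dLs = [
        np.array([[L[0, 0], 0.0], [0.0, 0.0]]),
        np.array([[0.0, 0.0], [1.0, 0.0]]),
        np.array([[0.0, 0.0], [0.0, L[1, 1]]]),
    ]
    dpsis = [dl @ L.T + L @ dl.T for dl in dLs]
    nvar = 4 if shared else 3 + n_times
    grad = np.zeros(nvar)
    gI, gS = gamma[:p], gamma[p:]
    for Z, U, Y, Vinv, pat in cache:
        mean = np.outer(U @ gI, Z[:, 0]) + np.outer(U @ gS, Z[:, 1])
        R = Y - mean
        Wv = R @ Vinv
        for a, dpsi in enumerate(dpsis):
            dV = Z @ dpsi @ Z.T
            grad[a] += pat["n"] * float(np.trace(Vinv @ dV)) \
                - float(np.einsum("ij,jk,ik->", Wv, dV, Wv))
        if shared:
            dv = sig2[0]
            grad[3] += dv * (pat["n"] * float(np.trace(Vinv))
                             - float(np.einsum("ij,ij->", Wv, Wv)))
        else:
            for local_t, t in enumerate(pat["times"]):
                dv = sig2[t]
                grad[3 + t] += dv * (pat["n"] * Vinv[local_t, local_t]
                                     - float((Wv[:, local_t] ** 2).sum()))
    return nll, 0.5 * grad, gamma, N


def _u_design(ds: MediationDataset):
    spec = ds.spec
    cols = [np.ones(ds.n), ds.x, ds.m1, ds.m2, ds.w]
    base_I = ["intercept_const", "c_I", "b1_I", "b2_I", "g_I"]
    base_S = ["slope_const", "c_S", "b1_S", "b2_S", "g_S"]
    for term, arr, nI, nS in (
        ("cw", ds.xw, "cw_I", "cw_S"),
        ("b1w", ds.m1w, "b1w_I", "b1w_S"),
        ("b2w", ds.m2w, "b2w_I", "b2w_S"),
    ):
        if term in spec.interactions:
            cols.append(arr)
            base_I.append(nI)
            base_S.append(nS)
    for j, c in enumerate(spec.covariates):
        cols.append(ds.cov[:, j])
        base_I.append(spec.cov_name(c, "I"))
        base_S.append(spec.cov_name(c, "S"))
    return np.column_stack(cols), base_I, base_S



def mediator_designs(ds: MediationDataset):
    """Regressor columns and coefficient names for the two mediator blocks."""
    spec = ds.spec
    ones = np.ones(ds.n)
    cols1 = [ones, ds.x, ds.w]
    names1 = ["tau_const", "a1", "g_tau"]
    if "a1w" in spec.interactions:
        cols1.append(ds.xw)
        names1.append("a1w")
    cols2 = [ones, ds.x, ds.m1, ds.w]
    names2 = ["fdg_const", "a2", "d21", "g_fdg"]
    if "a2w" in spec.interactions:
        cols2.append(ds.xw)
        names2.append("a2w")
    if "d21w" in spec.interactions:
        cols2.append(ds.m1w)
        names2.append("d21w")
    if spec.covariates_on_mediators:
        for j, c in enumerate(spec.covariates):
            cols1.append(ds.cov[:, j])
            names1.append(spec.cov_name(c, "tau"))
            cols2.append(ds.cov[:, j])
            names2.append(spec.cov_name(c, "fdg"))
    return cols1, names1, cols2, names2


def fit_growth_mediation(
    ds: MediationDataset,
    start_phi: np.ndarray | None = None,
    compute_variance_ses: bool = False,
    max_restarts: int = 5,
) -> MediationFit:
    """Maximum-likelihood fit of all three blocks of the structural model."""
    spec = ds.spec
    cols1, names1, cols2, names2 = mediator_designs(ds)
    coef1, se1, ll1, s2_1, np1 = _ols_block(ds.m1, cols1, names1)
    coef2, se2, ll2, s2_2, np2 = _ols_block(ds.m2, cols2, names2)

    # block 3: latent growth
    U, names_I, names_S = _u_design(ds)
    p = U.shape[1]
    loadings = np.asarray(spec.slope_loadings, dtype=float)
    n_times = len(spec.ef_cols)
    shared = spec.ef_residual == "shared"
    patterns = _growth_patterns(U, ds.ef, loadings)
    if not patterns:
        raise ValueError("no observed EF values in the analysis sample")

    if start_phi is not None:
        phi0 = np.asarray(start_phi, dtype=float)
    else:
        ef0 = ds.ef[:, 0]
        v = np.nanvar(ds.ef)
        v = v if np.isfinite(v) and v > 0 else 1.0
        phi0 = np.concatenate([
            [0.5 * np.log(0.4 * v), 0.0, 0.5 * np.log(0.02 * v)],
            np.full(1 if shared else n_times, np.log(0.4 * v)),
        ])

    def objective(phi):
        nll, grad, *_ = _growth_negll(phi, patterns, p, n_times, shared)
        return nll, grad

    bounds = [(-12.0, 8.0)] * len(phi0)
    bounds[1] = (-50.0, 50.0)  # off-diagonal Cholesky entry is unconstrained
    best = None
    rng = np.random.default_rng(12345)
    converged = False
    for attempt in range(max_restarts + 1):
        x0 = phi0 if attempt == 0 else phi0 + rng.normal(0, 0.5, len(phi0))
        res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-13,
                                         "gtol": 1e-9})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if res.success or np.max(np.abs(res.jac)) < 1e-3:
            converged = True
            best = res if res.fun <= best.fun + 1e-10 else best
            break
    if not converged:
        warnings.warn(
            f"growth block: optimizer not converged (|grad|max="
            f"{np.max(np.abs(best.jac)):.2e}); using best point",
            RuntimeWarning,
        )
    phi = best.x
    nll, _, gamma, N = _growth_negll(phi, patterns, p, n_times, shared,
                                     want_grad=True)
    ll3 = -nll
    L, psi_eta, sig2 = _phi_to_var(phi, n_times, shared)
    cov_gamma = np.linalg.inv(N)
    se_gamma = np.sqrt(np.maximum(np.diag(cov_gamma), 0.0))

    coeffs = {**coef1, **coef2}
    ses = {**se1, **se2}
    for j, nm in enumerate(names_I):
        coeffs[nm] = float(gamma[j])
        ses[nm] = float(se_gamma[j])
    for j, nm in enumerate(names_S):
        coeffs[nm] = float(gamma[p + j])
        ses[nm] = float(se_gamma[p + j])

    n_var = 4 if shared else 3 + n_times
    logliks = {
        "tau": ll1, "fdg": ll2, "growth": float(ll3),
        "total": float(ll1 + ll2 + ll3),
    }
    nparams = {"tau": np1, "fdg": np2, "growth": 2 * p + n_var,
               "total": np1 + np2 + 2 * p + n_var}

    if compute_variance_ses:
        # delta-method SEs for (psi_I, psi_IS, psi_S, theta_ef) via the
        # numerical Hessian of the profile likelihood
        def f(ph):
            return _growth_negll(ph, patterns, p, n_times, shared,
                                 want_grad=False)[0]
        from .likelihood import observed_info_se
        se_phi = observed_info_se(lambda ph: -f(ph), phi)
        # report on the internal scale; downstream consumers use points only
        for j, nm in enumerate(
            ["phi_log_chol_11", "phi_chol_21", "phi_log_chol_22"]
            + ([f"phi_log_theta_ef"] if shared else
               [f"phi_log_theta_ef_{t}" for t in range(n_times)])
        ):
            coeffs[nm] = float(phi[j])
            ses[nm] = float(se_phi[j])

    order = names1 + names2 + names_I + names_S
    extra = [k for k in coeffs if k not in order]
    order = order + extra
    return MediationFit(
        coefficients=pd.Series({k: coeffs[k] for k in order}),
        ses=pd.Series({k: ses[k] for k in order}),
        psi_eta=psi_eta,
        theta_ef=sig2 if not shared else sig2[:1],
        logliks=logliks,
        n_used=ds.n,
        converged=converged,
        phi=phi,
        nparams=nparams,
        x_sd=float(ds.x.std()),
        w_sd=float(ds.w.std()),
        covariate_means=ds.covariate_means,
        covariate_names=tuple(spec.covariates),
    )


def model_fit_indices(fit: MediationFit, ds: MediationDataset) -> FitIndices:
    """Fit statistics of the structural model against a saturated H1.

    H1 is the unrestricted multivariate regression of (M1, M2, EF0..EFT) on
    the exogenous columns (X, W, X*W, covariates) with an unstructured
    residual covariance, estimated under EF missingness via EM on the joint
    moments.  The baseline model has means and variances only.  SRMR
    compares the H1 residual covariance with the structural model's implied
    residual covariance (moderated paths evaluated at the sample mean of W).
    """
    spec = ds.spec
    exog = np.column_stack([ds.x, ds.w, ds.xw, ds.cov])
    q = exog.shape[1]
    outcomes = np.column_stack([ds.m1, ds.m2, ds.ef])
    T = len(spec.ef_cols)
    n_out = 2 + T
    joint = np.column_stack([exog, outcomes])
    labels = ([f"exog{j}" for j in range(q)]
              + ["m1", "m2"] + [f"ef{t}" for t in range(T)])
    em = em_saturated(joint, labels=labels)
    ll_joint = em.loglik
    # exogenous block is complete: closed-form saturated marginal
    mu_e = exog.mean(axis=0)
    cov_e = np.cov(exog, rowvar=False, bias=True)
    ll_exog = mvn_loglik_missing(exog, MvnModel(mu_e, cov_e, tuple(labels[:q])))
    ll_h1 = ll_joint - ll_exog
    nparam_h1 = n_out * (q + 1) + n_out * (n_out + 1) // 2

    ll_h0 = fit.logliks["total"]
    nparam_h0 = fit.nparams["total"]

    # baseline: independent outcomes, intercept-only
    ll_base = 0.0
    for j in range(n_out):
        col = outcomes[:, j]
        col = col[~np.isnan(col)]
        v = col.var()
        ll_base += -0.5 * len(col) * (np.log(2 * np.pi * v) + 1.0)
    nparam_base = 2 * n_out

    # observed residual covariance from the joint saturated moments
    S = em.model.cov
    Sxx = S[:q, :q]
    Sxy = S[:q, q:]
    Syy = S[q:, q:]
    resid_obs = Syy - Sxy.T @ np.linalg.solve(Sxx, Sxy)

    # implied residual covariance of the recursive system at W = mean(W)
    wbar = float(ds.w.mean())
    d21 = fit.coef("d21") + fit.coef("d21w") * wbar
    b1 = np.array([fit.coef("b1_I") + fit.coef("b1w_I") * wbar,
                   fit.coef("b1_S") + fit.coef("b1w_S") * wbar])
    b2 = np.array([fit.coef("b2_I") + fit.coef("b2w_I") * wbar,
                   fit.coef("b2_S") + fit.coef("b2w_S") * wbar])
    # ML residual variances of the mediator regressions
    def _resid_var(yv, cols):
        Xb = np.column_stack(cols)
        coefv, *_ = np.linalg.lstsq(Xb, yv, rcond=None)
        r = yv - Xb @ coefv
        return float(r @ r) / len(yv)

    cols1, _, cols2, _ = mediator_designs(ds)
    s2_1 = _resid_var(ds.m1, cols1)
    s2_2 = _resid_var(ds.m2, cols2)

    lam = np.asarray(spec.slope_loadings)
    Zfull = np.column_stack([np.ones(T), lam])
    theta = fit.theta_ef if fit.theta_ef.size == T else np.full(T, fit.theta_ef[0])
    # linear map from independent components (e1, e2, zI, zS, eps_0..T-1)
    Tm = np.zeros((n_out, 4 + T))
    Tm[0, 0] = 1.0                                   # m1 = e1
    Tm[1, 0] = d21
    Tm[1, 1] = 1.0                                   # m2 = d21 e1 + e2
    eta_from = np.zeros((2, 4 + T))
    eta_from[:, 0] = b1 + b2 * d21                   # via m1 residual
    eta_from[:, 1] = b2                              # via m2 residual
    eta_from[0, 2] = 1.0
    eta_from[1, 3] = 1.0
    for t in range(T):
        Tm[2 + t, :] = Zfull[t, 0] * eta_from[0] + Zfull[t, 1] * eta_from[1]
        Tm[2 + t, 4 + t] += 1.0
    D = np.diag(np.concatenate([[s2_1, s2_2],
                                [fit.psi_eta[0, 0], fit.psi_eta[1, 1]],
                                theta]))
    D[2, 3] = D[3, 2] = 0.0
    Dfull = D.copy()
    Dfull[2, 3] = Dfull[3, 2] = fit.psi_eta[0, 1]
    resid_imp = Tm @ Dfull @ Tm.T

    out_labels = tuple(labels[q:])
    zero = np.zeros(n_out)
    srmr_val = srmr(
        MvnModel(zero, (resid_obs + resid_obs.T) / 2, out_labels),
        MvnModel(zero, (resid_imp + resid_imp.T) / 2, out_labels),
    )
    idx = fit_indices(
        loglik_h0=ll_h0, nparam_h0=nparam_h0,
        loglik_h1=ll_h1, nparam_h1=nparam_h1,
        loglik_base=ll_base, nparam_base=nparam_base,
        n=ds.n, srmr_value=srmr_val,
    )
    fit.fit = idx
    return idx


def predict_trajectories(
    fit: MediationFit,
    x_levels=(-1.0, 0.0, 1.0),
    w_levels=(-1.0, 0.0, 1.0),
    times=None,
) -> pd.DataFrame:
    """Model-implied M1, M2 and EF trajectories on an (X, W) grid.

    Levels are on the analysis scale of X and W (z-units for X by default);
    covariates are held at their analysis-sample means.  Grid points beyond
    4 SD of either variable trigger an extrapolation warning.
    """
    times = np.arange(len(fit.theta_ef) if fit.theta_ef.size > 1 else 8) \
        if times is None else np.asarray(times)
    for lv, sd, nm in ((x_levels, fit.x_sd, "X"), (w_levels, fit.w_sd, "W")):
        if np.max(np.abs(lv)) > 4.0 * max(sd, 1e-12):
            warnings.warn(f"{nm} grid extends beyond 4 SD: extrapolation",
                          RuntimeWarning)
    cov_I = sum(
        fit.coef(f"cov_{c.removesuffix('_c')}_I") * m
        for c, m in zip(fit.covariate_names, fit.covariate_means)
    )
    cov_S = sum(
        fit.coef(f"cov_{c.removesuffix('_c')}_S") * m
        for c, m in zip(fit.covariate_names, fit.covariate_means)
    )
    rows = []
    for xv in np.atleast_1d(x_levels):
        for wv in np.atleast_1d(w_levels):
            m1 = (fit.coef("tau_const") + fit.coef("a1") * xv
                  + fit.coef("g_tau") * wv + fit.coef("a1w") * xv * wv)
            m2 = (fit.coef("fdg_const") + fit.coef("a2") * xv
                  + fit.coef("d21") * m1 + fit.coef("g_fdg") * wv
                  + fit.coef("a2w") * xv * wv + fit.coef("d21w") * m1 * wv)
            I = (fit.coef("intercept_const") + fit.coef("c_I") * xv
                 + fit.coef("b1_I") * m1 + fit.coef("b2_I") * m2
                 + fit.coef("g_I") * wv + fit.coef("cw_I") * xv * wv
                 + fit.coef("b1w_I") * m1 * wv + fit.coef("b2w_I") * m2 * wv
                 + cov_I)
            Sv = (fit.coef("slope_const") + fit.coef("c_S") * xv
                  + fit.coef("b1_S") * m1 + fit.coef("b2_S") * m2
                  + fit.coef("g_S") * wv + fit.coef("cw_S") * xv * wv
                  + fit.coef("b1w_S") * m1 * wv + fit.coef("b2w_S") * m2 * wv
                  + cov_S)
            for t in times:
                rows.append({
                    "x": float(xv), "w": float(wv), "t": int(t),
                    "m1": m1, "m2": m2,
                    "ef": I + (t - 3) * Sv,
                    "intercept": I, "slope": Sv,
                })
    return pd.DataFrame(rows)
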