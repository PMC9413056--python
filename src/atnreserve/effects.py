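"""Conditional indirect effects, index of moderated mediation, bootstrap
confidence intervals and multiple-imputation pooling.

For the two-mediator serial system the indirect effects of the amyloid
ratio X on an executive-function growth factor Y (intercept or slope) at a
moderator value w are products of conditional path coefficients:

* ``B_AT(w)  = (a1 + a1w*w) * (b1_Y + b1w_Y*w)``
* ``B_ATN(w) = (a1 + a1w*w) * (d21 + d21w*w) * (b2_Y + b2w_Y*w)``
* ``B_AN(w)  = (a2 + a2w*w) * (b2_Y + b2w_Y*w)``

with direct effect ``c_Y + cw_Y*w``; the total effect is their sum (an
algebraic identity of the recursive linear system).  The index of moderated
mediation (IMM) is the derivative of a conditional indirect effect with
respect to w; when a pathway has a single moderated path it reduces to the
familiar product (e.g., ``a2w*b2_Y`` for B_AN).

Inference follows a two-track design: symmetric CIs pooled across
plausible-value imputations by Rubin's rules (Barnard-Rubin degrees of
freedom), and bias-corrected case bootstrap CIs for the indirect effects
computed with the per-subject mean plausible value as the moderator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mediation import (
    MediationDataset,
    MediationFit,
    MediationSpec,
    build_design,
    fit_growth_mediation,
)

__all__ = [
    "EffectEstimates",
    "PooledEstimate",
    "indirect_effects",
    "index_of_moderated_mediation",
    "bc_bootstrap",
    "bc_interval",
    "pool_rubin",
    "run_mi_inference",
    "MiInferenceResult",
    "effect_quantities",
    "imm_value",
]

PATHWAYS = ("AT", "ATN", "AN")
OUTCOMES = ("I", "S")


@dataclass
class EffectEstimates:
    """Point values of direct/indirect/total effects on a moderator grid."""

    table: pd.DataFrame        # columns: outcome, w, direct, b_at, b_atn, b_an, total
    w_grid: np.ndarray


def _getter(source):
    """Coefficient lookup (name -> scalar or array, absent terms read as 0)."""
    if callable(source):
        return source
    return lambda name: source.get(name, 0.0)


def _paths(coef, outcome: str, w: float):
    """Conditional path coefficients at moderator value w.

    ``coef`` is a lookup (callable or mapping); values may be scalars or
    arrays (the bootstrap evaluates all resamples at once).
    """
    coef = _getter(coef)
    a1 = coef("a1") + coef("a1w") * w
    a2 = coef("a2") + coef("a2w") * w
    d21 = coef("d21") + coef("d21w") * w
    b1 = coef(f"b1_{outcome}") + coef(f"b1w_{outcome}") * w
    b2 = coef(f"b2_{outcome}") + coef(f"b2w_{outcome}") * w
    c = coef(f"c_{outcome}") + coef(f"cw_{outcome}") * w
    return a1, a2, d21, b1, b2, c


def imm_value(coef, pathway: str, outcome: str, at_w: float = 0.0):
    """Derivative of the conditional indirect effect with respect to W."""
    coef = _getter(coef)
    a1, a2, d21, b1, b2, _ = _paths(coef, outcome, at_w)
    da1, da2 = coef("a1w"), coef("a2w")
    dd21 = coef("d21w")
    db1, db2 = coef(f"b1w_{outcome}"), coef(f"b2w_{outcome}")
    if pathway == "AT":
        return da1 * b1 + a1 * db1
    if pathway == "AN":
        return da2 * b2 + a2 * db2
    return da1 * d21 * b2 + a1 * dd21 * b2 + a1 * d21 * db2


def effect_quantities(coef, w_grid) -> dict:
    """Every reported effect quantity (works on scalar or array coefficients)."""
    coef = _getter(coef)
    out = {}
    for outcome in OUTCOMES:
        for w in np.atleast_1d(w_grid):
            a1, a2, d21, b1, b2, c = _paths(coef, outcome, float(w))
            b_at, b_atn, b_an = a1 * b1, a1 * d21 * b2, a2 * b2
            tag = f"{outcome}_w{float(w):+.2f}"
            out[f"direct_{tag}"] = c
            out[f"b_at_{tag}"] = b_at
            out[f"b_atn_{tag}"] = b_atn
            out[f"b_an_{tag}"] = b_an
            out[f"total_{tag}"] = c + b_at + b_atn + b_an
    for pathway in PATHWAYS:
        for outcome in OUTCOMES:
            out[f"imm_{pathway}_{outcome}"] = imm_value(coef, pathway, outcome, 0.0)
    return out


def indirect_effects(fit: MediationFit, w_grid=(-1.0, 0.0, 1.0)) -> EffectEstimates:
    """Direct, indirect and total effects of X per outcome over a W grid."""
    rows = []
    w_grid = np.atleast_1d(np.asarray(w_grid, dtype=float))
    for outcome in OUTCOMES:
        for w in w_grid:
            a1, a2, d21, b1, b2, c = _paths(fit.coef, outcome, w)
            b_at = a1 * b1
            b_atn = a1 * d21 * b2
            b_an = a2 * b2
            rows.append({
                "outcome": outcome, "w": float(w),
                "direct": c, "b_at": b_at, "b_atn": b_atn, "b_an": b_an,
                "total": c + b_at + b_atn + b_an,
            })
    return EffectEstimates(table=pd.DataFrame(rows), w_grid=w_grid)


def index_of_moderated_mediation(
    fit: MediationFit, pathway: str, outcome: str, at_w: float = 0.0
) -> float:
    """Derivative of the conditional indirect effect with respect to W.

    Constant in ``at_w`` (and equal to the classic product, e.g.
    ``a2w * b2``) whenever at most one path on the pathway is moderated.
    """
    if pathway not in PATHWAYS:
        raise ValueError(f"pathway must be one of {PATHWAYS}")
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    return float(imm_value(fit.coef, pathway, outcome, at_w))


@dataclass
class BootstrapCI:
    """Bias-corrected bootstrap interval for one quantity."""

    estimate: float
    lo: float
    hi: float
    z0: float
    n_boot: int
    n_failed: int


def bc_bootstrap(
    ds: MediationDataset,
    estimator,
    B: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, BootstrapCI]:
    """Bias-corrected case bootstrap over subjects.

    ``estimator`` maps a :class:`MediationDataset` to a dict of scalar
    quantities; subjects are resampled with replacement and every quantity
    re-estimated per resample.  The bias correction shifts the percentile
    levels by the probit of the bootstrap distribution's position relative
    to the full-sample estimate (half weight on ties); with a symmetric
    distribution centred on the estimate it reduces to the percentile
    method exactly.  Failed resamples are dropped (error above 5%).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    point = estimator(ds)
    names = list(point.keys())
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 577]))
    n = ds.n
    idx_all = rng.integers(0, n, size=(B, n))
    if hasattr(estimator, "batch"):
        batched = estimator.batch(ds, idx_all)
        ok = np.ones(B, dtype=bool)
        for k in names:
            ok &= np.isfinite(np.asarray(batched[k]))
        failed = int(B - ok.sum())
        draws = {k: list(np.asarray(batched[k])[ok]) for k in names}
    else:
        draws = {k: [] for k in names}
        failed = 0
        for b in range(B):
            try:
                est = estimator(ds.take(idx_all[b]))
            except Exception:
                failed += 1
                continue
            for k in names:
                draws[k].append(est[k])
    if failed > 0.05 * B:
        raise RuntimeError(f"{failed}/{B} bootstrap resamples failed")
    out = {}
    for k in names:
        theta_star = np.asarray(draws[k], dtype=float)
        lo, hi, z0 = bc_interval(theta_star, point[k], alpha, warn_name=k)
        out[k] = BootstrapCI(float(point[k]), lo, hi, z0, theta_star.size, failed)
    return out


def bc_interval(theta_star: np.ndarray, theta_hat: float, alpha: float = 0.05,
                warn_name: str = ""):
    """Bias-corrected percentile interval from bootstrap draws.

    ``z0`` is the probit of the fraction of draws below the point estimate
    (ties get half weight); the percentile levels are shifted by ``2*z0``.
    With ``z0 = 0`` the endpoints equal the plain percentile interval on the
    same draws.  A degenerate distribution yields the collapsed interval
    ``[c, c]`` with a warning.
    """
    theta_star = np.asarray(theta_star, dtype=float)
    bb = theta_star.size
    if np.allclose(theta_star, theta_star[0]):
        warnings.warn(f"degenerate bootstrap distribution {warn_name}".strip(),
                      RuntimeWarning)
        c = float(theta_star[0])
        return c, c, 0.0
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    p_less = ((theta_star < theta_hat).sum()
              + 0.5 * (theta_star == theta_hat).sum()) / bb
    p_less = float(np.clip(p_less, 0.5 / bb, 1.0 - 0.5 / bb))
    z0 = float(stats.norm.ppf(p_less))
    q_lo = stats.norm.cdf(2.0 * z0 - z_crit)
    q_hi = stats.norm.cdf(2.0 * z0 + z_crit)
    return float(np.quantile(theta_star, q_lo)), float(np.quantile(theta_star, q_hi)), z0


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of one quantity across M imputations."""

    qbar: float
    ubar: float        # mean within-imputation variance
    b: float           # between-imputation variance
    t: float           # total variance
    df: float          # Barnard-Rubin degrees of freedom
    ci: tuple[float, float]
    M: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.t))


def pool_rubin(
    estimates: np.ndarray,
    ses: np.ndarray,
    alpha: float = 0.05,
    nu_com: float | None = None,
) -> list[PooledEstimate]:
    """Pool an M x p matrix of estimates and standard errors.

    Total variance is ``ubar + (1 + 1/M) * b``; degrees of freedom follow
    Barnard-Rubin when a complete-data df ``nu_com`` is supplied, otherwise
    the classic large-sample formula.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    se = np.atleast_2d(np.asarray(ses, dtype=float))
    if est.shape != se.shape:
        raise ValueError("estimates and ses must have identical shape")
    M = est.shape[0]
    if M < 2:
        raise ValueError("pooling undefined for M < 2; report the single fit")
    if not (np.isfinite(est).all() and np.isfinite(se).all()):
        raise ValueError("non-finite entries in estimates or ses")
    out = []
    for j in range(est.shape[1]):
        q = est[:, j]
        qbar = float(q.mean())
        b = float(q.var(ddof=1))
        ubar = float((se[:, j] ** 2).mean())
        t = ubar + (1.0 + 1.0 / M) * b
        if b <= 0.0 or t <= 0.0:
            df = np.inf if nu_com is None else float(nu_com)
        else:
            with np.errstate(divide="ignore", over="ignore"):
                r = np.float64((1.0 + 1.0 / M) * b / ubar) if ubar > 0 else np.inf
                nu_old = float((M - 1) * np.square(1.0 + 1.0 / r)) \
                    if np.isfinite(r) else M - 1.0
            if nu_com is None or not np.isfinite(nu_com):
                df = float(nu_old)
            else:
                lam = (1.0 + 1.0 / M) * b / t
                nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
                df = float(1.0 / (1.0 / nu_old + 1.0 / nu_obs))
        crit = stats.t.ppf(1.0 - alpha / 2.0, df) if np.isfinite(df) \
            else stats.norm.ppf(1.0 - alpha / 2.0)
        half = crit * np.sqrt(t)
        out.append(PooledEstimate(
            qbar=qbar, ubar=ubar, b=b, t=float(t), df=float(df),
            ci=(qbar - half, qbar + half), M=M,
        ))
    return out


def _effects_quantities(fit: MediationFit, w_grid) -> dict[str, float]:
    """Flat dict of every reported effect quantity for bootstrapping."""
    return {k: float(v) for k, v in effect_quantities(fit.coef, w_grid).items()}


@dataclass
class MiInferenceResult:
    """Pooled coefficients plus bootstrap effect CIs."""

    pooled: pd.DataFrame            # per coefficient: qbar, se, df, ci, b, ubar
    effects: EffectEstimates        # point effects at the mean plausible value
    boot: pd.DataFrame              # per quantity: estimate, lo, hi, z0
    mean_w_fit: MediationFit
    per_imputation: pd.DataFrame    # coefficient estimates per imputation


def run_mi_inference(
    values: np.ndarray,
    table: pd.DataFrame,
    spec: MediationSpec,
    w_grid=(-1.0, 0.0, 1.0),
    B: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    boot_variance_params: bool = False,
) -> MiInferenceResult:
    """Two-track inference across plausible-value imputations.

    The mediation model is fitted once per imputation (moderator = that
    column of ``values``) and the coefficients pooled by Rubin's rules;
    bias-corrected bootstrap CIs for the indirect effects and the IMM use
    the per-subject mean plausible value as the moderator.
    ``values`` must be row-aligned with ``table``.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != len(table):
        raise ValueError("plausible values and table are not row-aligned")
    M = values.shape[1]
    work = table.copy()
    work.attrs = dict(table.attrs)

    ests, ses_l = [], []
    names = None
    phi = None
    for m in range(M):
        work[spec.w_col] = values[:, m]
        ds_m = build_design(work, spec)
        try:
            fit_m = fit_growth_mediation(ds_m, start_phi=phi)
        except Exception as exc:
            raise RuntimeError(f"fit failed for imputation column {m + 1}") from exc
        phi = fit_m.phi
        if names is None:
            names = list(fit_m.coefficients.index)
        ests.append(fit_m.coefficients.reindex(names).to_numpy())
        ses_l.append(fit_m.ses.reindex(names).to_numpy())
        n_used = fit_m.n_used
    est = np.vstack(ests)
    sev = np.vstack(ses_l)
    if M >= 2:
        pooled = pool_rubin(est, sev, alpha=alpha, nu_com=n_used - 1)
        pooled_df = pd.DataFrame({
            "coefficient": names,
            "estimate": [p.qbar for p in pooled],
            "se": [p.se for p in pooled],
            "df": [p.df for p in pooled],
            "ci_lo": [p.ci[0] for p in pooled],
            "ci_hi": [p.ci[1] for p in pooled],
            "between_var": [p.b for p in pooled],
            "within_var": [p.ubar for p in pooled],
        })
    else:
        pooled_df = pd.DataFrame({
            "coefficient": names,
            "estimate": est[0],
            "se": sev[0],
            "df": np.inf,
            "ci_lo": est[0] - 1.96 * sev[0],
            "ci_hi": est[0] + 1.96 * sev[0],
            "between_var": 0.0,
            "within_var": sev[0] ** 2,
        })

    # bootstrap track: moderator = mean plausible value
    work[spec.w_col] = values.mean(axis=1)
    ds_bar = build_design(work, spec)
    fit_bar = fit_growth_mediation(ds_bar)

    from ._fastboot import GrowthEffectsEstimator  # deferred: avoids cycle

    if spec.ef_residual == "shared":
        estimator = GrowthEffectsEstimator(w_grid, warm_phi=fit_bar.phi)
    else:
        warm = fit_bar.phi

        def estimator(d: MediationDataset) -> dict[str, float]:
            f = fit_growth_mediation(d, start_phi=warm, max_restarts=0)
            return _effects_quantities(f, w_grid)

    boot = bc_bootstrap(ds_bar, estimator, B=B, alpha=alpha, seed=seed)
    boot_df = pd.DataFrame({
        "quantity": list(boot.keys()),
        "estimate": [c.estimate for c in boot.values()],
        "ci_lo": [c.lo for c in boot.values()],
        "ci_hi": [c.hi for c in boot.values()],
        "z0": [c.z0 for c in boot.values()],
    })
    per_imp = pd.DataFrame(est, columns=names)
    per_imp.insert(0, "imputation", np.arange(1, M + 1))
    return MiInferenceResult(
        pooled=pooled_df,
        effects=indirect_effects(fit_bar, w_grid),
        boot=boot_df,
        mean_w_fit=fit_bar,
        per_imputation=per_imp,
    )
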