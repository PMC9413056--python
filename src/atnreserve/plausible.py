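"""Bayesian re-estimation of the decomposition model and plausible-value
imputation of the latent reserve score.

A Gibbs sampler re-estimates the decomposition model: the per-subject
latent reserve values are drawn from their normal full conditional, the
regression coefficients from a conjugate normal, the reserve variance from
a conjugate inverse-gamma, and the memory error variance ``theta`` from a
Metropolis step targeting a highly informative truncated-normal prior
(N(0.161, 0.00002), truncated to positives) times the likelihood.  The
saturated predictor moments carry a conjugate normal-inverse-Wishart
(Jeffreys) posterior and are drawn each sweep; missing predictor cells are
drawn from their conditional normals under the current moment draw.

Convergence is monitored with the Gelman-Rubin potential scale reduction
factor on the second half of each chain; model adequacy with a posterior
predictive p-value based on a likelihood-ratio discrepancy; and the
reliability of the saved plausible values with the intraclass correlation
ICC(2,k) (two-way random effects, absolute agreement, mean of k ratings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import invwishart

from .decomposition import DecompositionFit, DecompositionSpec, fit_decomposition_ml
from .likelihood import MvnModel, em_saturated, mvn_loglik_missing

__all__ = [
    "McmcConfig",
    "GibbsChains",
    "PlausibleValueSet",
    "gibbs_decomposition",
    "psrf",
    "ppp",
    "draw_plausible_values",
    "icc2k",
]


@dataclass
class McmcConfig:
    """Sampler configuration.

    ``iterations`` counts total sweeps per chain; the first
    ``burn_in_fraction`` of each chain is discarded.  ``prior_theta`` is the
    (mean, variance) of the truncated-normal prior on the memory error
    variance; ``prior_beta_var`` the variance of the diffuse normal
    coefficient prior; ``prior_psi`` the (shape, rate) of the diffuse
    inverse-gamma prior on the reserve variance.
    """

    n_chains: int = 2
    iterations: int = 2000
    burn_in_fraction: float = 0.5
    thin: int = 1
    seed: int = 0
    prior_theta: tuple[float, float] = (0.161, 0.00002)
    prior_beta_var: float = 1e6
    prior_psi: tuple[float, float] = (0.001, 0.001)
    theta_proposal_sd: float = 0.004
    max_stored_latent: int = 240

    def __post_init__(self):
        if self.n_chains < 1 or self.iterations < 10:
            raise ValueError("need >=1 chain and >=10 iterations")
        if not (0.0 < self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must be in (0,1)")
        if self.prior_theta[1] <= 0 or self.prior_beta_var <= 0:
            raise ValueError("prior variances must be > 0")


@dataclass
class GibbsChains:
    """Posterior draws from :func:`gibbs_decomposition`.

    ``params[c]`` maps parameter name -> (retained_iterations,) draws for
    chain ``c`` (post burn-in).  A thinned subset of the latent reserve
    vectors is stored in ``latent``, with bookkeeping of which chain and
    retained iteration each stored vector came from.
    """

    params: list[dict[str, np.ndarray]]
    latent: np.ndarray                  # (n_stored, n_subjects)
    latent_chain: np.ndarray            # (n_stored,)
    latent_iter: np.ndarray             # (n_stored,) index within retained draws
    n_retained: int
    spec: DecompositionSpec
    config: McmcConfig
    mu_store: np.ndarray = None         # (n_chains, n_retained, p)
    sigma_store: np.ndarray = None      # (n_chains, n_retained, p, p)
    ml_fit: DecompositionFit = None
    data: np.ndarray = field(repr=False, default=None)   # (n, p+1) with NaN
    labels: tuple[str, ...] = ()

    def stacked(self, name: str) -> np.ndarray:
        """(n_chains, n_retained) draws of one parameter."""
        return np.stack([c[name] for c in self.params])

    @property
    def param_names(self) -> list[str]:
        return list(self.params[0].keys())


def _missing_patterns(mask):
    """Row groups sharing one observed-predictor pattern."""
    groups = []
    for pattern in np.unique(mask, axis=0):
        rows = np.flatnonzero((mask == pattern).all(axis=1))
        obs = pattern.astype(bool)
        groups.append((rows, obs, ~obs))
    return groups


def _impute_missing_x(Ximp, groups, mu_x, sxx, rng,
                      y=None, memr=None, beta=None, theta=None):
    """Draw missing predictor cells from their full conditional normals.

    The conditional combines the saturated predictor model (prior given the
    observed predictors) with, when the regression state is supplied, the
    memory equation ``y - memr = b0 + beta'x + e`` as a rank-one Gaussian
    likelihood update -- the proper Gibbs full conditional.
    """
    use_y = y is not None
    for rows, obs, miss in groups:
        if not miss.any():
            continue
        m = int(miss.sum())
        if obs.any():
            Soo = sxx[np.ix_(obs, obs)]
            Smo = sxx[np.ix_(miss, obs)]
            B = np.linalg.solve(Soo, Smo.T).T
            C0 = sxx[np.ix_(miss, miss)] - B @ Smo.T
            dev = Ximp[np.ix_(rows, obs)] - mu_x[obs]
            m0 = mu_x[miss] + dev @ B.T
        else:
            C0 = sxx[np.ix_(miss, miss)].copy()
            m0 = np.broadcast_to(mu_x[miss], (len(rows), m)).copy()
        C0 = C0 + 1e-10 * np.eye(m)
        if use_y:
            b_mis = beta[1:][miss]
            y_rows = y[rows]
            has_y = ~np.isnan(y_rows)
            if np.any(b_mis != 0.0) and has_y.any():
                C0_inv = np.linalg.inv(C0)
                prec = C0_inv + np.outer(b_mis, b_mis) / theta
                C1 = np.linalg.inv(prec)
                b_obs = beta[1:][obs]
                resid = (y_rows - memr[rows] - beta[0]
                         - Ximp[np.ix_(rows, obs)] @ b_obs)
                mean1 = (m0 @ C0_inv.T + np.outer(
                    np.where(has_y, resid, 0.0), b_mis) / theta) @ C1.T
                chol1 = np.linalg.cholesky(C1)
                chol0 = np.linalg.cholesky(C0)
                z = rng.standard_normal((len(rows), m))
                draw_y = mean1 + z @ chol1.T
                draw_no_y = m0 + z @ chol0.T
                Ximp[np.ix_(rows, miss)] = np.where(
                    has_y[:, None], draw_y, draw_no_y
                )
                continue
        chol = np.linalg.cholesky(C0)
        z = rng.standard_normal((len(rows), m))
        Ximp[np.ix_(rows, miss)] = m0 + z @ chol.T


def gibbs_decomposition(
    table: pd.DataFrame,
    spec: DecompositionSpec,
    mcmc: McmcConfig,
    ml_fit: DecompositionFit | None = None,
) -> GibbsChains:
    """Run the Gibbs sampler for the decomposition model.

    Starting values are the ML estimates; draws are seed-deterministic.
    """
    if ml_fit is None:
        ml_fit = fit_decomposition_ml(table, spec)
    cols = list(spec.predictors) + [spec.mem_col]
    data = table[cols].to_numpy(dtype=float)
    X = data[:, :-1]
    y = data[:, -1]
    n, p = X.shape
    mask = ~np.isnan(X)
    y_obs = ~np.isnan(y)
    n_y = int(y_obs.sum())

    mu_x_ml, sxx_ml = ml_fit.predictor_mean, ml_fit.predictor_cov
    groups = _missing_patterns(mask)
    any_missing_x = not mask.all()
    if n <= p + 2:
        raise ValueError("too few rows for the predictor-moment posterior")

    a_psi, b_psi = mcmc.prior_psi
    th_mean, th_var = mcmc.prior_theta
    prior_prec_beta = 1.0 / mcmc.prior_beta_var

    n_burn = int(mcmc.iterations * mcmc.burn_in_fraction)
    n_keep = mcmc.iterations - n_burn
    store_every = max(1, int(np.ceil(n_keep * mcmc.n_chains / mcmc.max_stored_latent)))

    chains = []
    mu_stores, sigma_stores = [], []
    latent_rows, latent_chain, latent_iter = [], [], []
    ss = np.random.SeedSequence([int(mcmc.seed) % (2**31), 911])
    chain_seeds = ss.spawn(mcmc.n_chains)

    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        beta = np.concatenate([[ml_fit.intercept], ml_fit.beta.to_numpy()])
        # small chain-specific jitter so chains do not start identically
        beta = beta + 0.01 * rng.standard_normal(p + 1) * (1.0 + np.abs(beta))
        psi = max(ml_fit.psi_hat, 1e-3) * float(np.exp(0.1 * rng.standard_normal()))
        theta = th_mean
        mu_x, sxx = mu_x_ml.copy(), sxx_ml.copy()
        memr = np.zeros(n)
        Ximp = np.where(mask, X, 0.0)
        if any_missing_x:
            _impute_missing_x(Ximp, groups, mu_x, sxx, rng)

        keep: dict[str, list] = {f"beta_{nm}": [] for nm in ["intercept", *spec.predictors]}
        keep.update({"psi": [], "theta": []})
        mu_keep = np.empty((n_keep, p))
        sigma_keep = np.empty((n_keep, p, p))
        n_acc = 0

        for it in range(mcmc.iterations):
            # (0) saturated predictor moments: conjugate NIW (Jeffreys) draw
            xbar = Ximp.mean(axis=0)
            S_ml = (Ximp - xbar).T @ (Ximp - xbar) / n
            sxx = invwishart.rvs(df=n - 1, scale=n * S_ml, random_state=rng)
            sxx = np.atleast_2d(sxx)
            mu_x = xbar + np.linalg.cholesky(sxx / n) @ rng.standard_normal(p)

            # (v) missing predictor cells under the current moment draw,
            # conditioning on the memory equation (full conditional)
            if any_missing_x:
                _impute_missing_x(Ximp, groups, mu_x, sxx, rng,
                                  y=y, memr=memr, beta=beta, theta=theta)

            D = np.column_stack([np.ones(n), Ximp])
            linpred = D @ beta

            # (i) latent reserve values
            lam = psi / (psi + theta)
            cond_sd = np.sqrt(psi * theta / (psi + theta))
            memr = np.where(
                y_obs,
                lam * (np.where(y_obs, y, 0.0) - linpred),
                0.0,
            ) + np.where(y_obs, cond_sd, np.sqrt(psi)) * rng.standard_normal(n)

            # (ii) coefficients given (y - memr)
            Do = D[y_obs]
            ystar = y[y_obs] - memr[y_obs]
            prec = Do.T @ Do / theta + prior_prec_beta * np.eye(p + 1)
            cov = np.linalg.inv(prec)
            mean_b = cov @ (Do.T @ ystar) / theta
            beta = mean_b + np.linalg.cholesky(cov) @ rng.standard_normal(p + 1)

            # (iii) reserve variance
            psi = 1.0 / rng.gamma(a_psi + 0.5 * n, 1.0 / (b_psi + 0.5 * float(memr @ memr)))

            # (iv) error variance (Metropolis, truncated-normal prior)
            resid2 = float(((ystar - Do @ beta) ** 2).sum())

            def log_post_theta(t):
                if t <= 0:
                    return -np.inf
                return (
                    -0.5 * n_y * np.log(t)
                    - 0.5 * resid2 / t
                    - 0.5 * (t - th_mean) ** 2 / th_var
                )

            prop = theta + mcmc.theta_proposal_sd * rng.standard_normal()
            if np.log(rng.random()) < log_post_theta(prop) - log_post_theta(theta):
                theta = prop
                n_acc += 1
            if not np.isfinite(log_post_theta(theta)):
                raise FloatingPointError(
                    f"non-finite posterior density at iteration {it} (chain {c})"
                )

            if it >= n_burn:
                r = it - n_burn
                keep["beta_intercept"].append(beta[0])
                for j, nm in enumerate(spec.predictors):
                    keep[f"beta_{nm}"].append(beta[j + 1])
                keep["psi"].append(psi)
                keep["theta"].append(theta)
                mu_keep[r] = mu_x
                sigma_keep[r] = sxx
                if r % store_every == 0:
                    latent_rows.append(memr.copy())
                    latent_chain.append(c)
                    latent_iter.append(r)

        chains.append({k: np.asarray(v) for k, v in keep.items()})
        mu_stores.append(mu_keep)
        sigma_stores.append(sigma_keep)

    return GibbsChains(
        params=chains,
        latent=np.asarray(latent_rows),
        latent_chain=np.asarray(latent_chain),
        latent_iter=np.asarray(latent_iter),
        n_retained=n_keep,
        spec=spec,
        config=mcmc,
        mu_store=np.asarray(mu_stores),
        sigma_store=np.asarray(sigma_stores),
        ml_fit=ml_fit,
        data=data,
        labels=tuple(cols),
    )


def psrf(draws, second_half: bool = True, split: bool = False) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``draws`` is (n_chains, n_iterations).  By default the statistic is
    computed on the second 50% of iterations; ``split`` additionally halves
    each chain.  When both the within- and between-chain variances are zero
    (constant parameter) the convention is to return 1.
    """
    arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2:
        raise ValueError("draws must be (n_chains, n_iterations)")
    if second_half:
        arr = arr[:, arr.shape[1] // 2:]
    if split:
        half = arr.shape[1] // 2
        arr = np.concatenate([arr[:, :half], arr[:, half: 2 * half]], axis=0)
    m, n = arr.shape
    if m < 2:
        raise ValueError("need >= 2 chains (use split=True for one chain)")
    if n < 10:
        raise ValueError("need >= 10 retained draws per chain")
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0.0 and B == 0.0:
        return 1.0
    if W == 0.0:
        return np.inf
    return float(np.sqrt((n - 1) / n + B / (n * W)))


def chains_psrf(chains: GibbsChains) -> dict[str, float]:
    """PSRF of every retained model parameter."""
    return {name: psrf(chains.stacked(name)) for name in chains.param_names}


def _model_implied(mu_x, sxx, beta_full, psi, theta, labels) -> MvnModel:
    p = len(mu_x)
    b0, b = beta_full[0], beta_full[1:]
    mean = np.concatenate([mu_x, [b0 + b @ mu_x]])
    cov = np.zeros((p + 1, p + 1))
    cov[:p, :p] = sxx
    cov[:p, p] = cov[p, :p] = sxx @ b
    cov[p, p] = b @ sxx @ b + psi + theta
    return MvnModel(mean, cov, tuple(labels))


def ppp(
    chains: GibbsChains,
    n_draws: int = 100,
    seed: int = 0,
    em_tol: float = 1e-6,
) -> float:
    """Posterior predictive p-value with a likelihood-ratio discrepancy.

    For each selected posterior draw, the discrepancy of a dataset is twice
    the gap between its saturated (EM) log-likelihood and its log-likelihood
    under the draw's model-implied moments; the PPP is the proportion of
    draws for which a replicate dataset (same size and missingness pattern,
    simulated from the draw) is at least as discrepant as the observed data.
    """
    data = chains.data
    labels = chains.labels
    n, p1 = data.shape
    p = p1 - 1
    mask = ~np.isnan(data)

    total = chains.n_retained * len(chains.params)
    if total < 50:
        warnings.warn("fewer than 50 retained draws: PPP is imprecise", RuntimeWarning)
    n_draws = min(n_draws, total)
    # equally spaced draws alternating across chains
    sel = np.linspace(0, total - 1, n_draws).astype(int)
    names = ["beta_intercept"] + [f"beta_{nm}" for nm in chains.spec.predictors]

    obs_sat = em_saturated(data, tol=em_tol, labels=list(labels))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 313]))
    count = 0
    for s in sel:
        c, r = s % len(chains.params), s // len(chains.params)
        beta_full = np.array([chains.params[c][nm][r] for nm in names])
        psi = chains.params[c]["psi"][r]
        theta = chains.params[c]["theta"][r]
        mu_x = chains.mu_store[c, r]
        sxx = chains.sigma_store[c, r]
        model = _model_implied(mu_x, sxx, beta_full, psi, theta, labels)
        d_obs = 2.0 * (obs_sat.loglik - mvn_loglik_missing(data, model))

        rep = rng.multivariate_normal(model.mean, model.cov, size=n, method="eigh")
        rep[~mask] = np.nan
        rep_sat = em_saturated(rep, tol=em_tol, labels=list(labels))
        d_rep = 2.0 * (rep_sat.loglik - mvn_loglik_missing(rep, model))
        if d_rep >= d_obs:
            count += 1
    return count / n_draws


def discrepancy(data, model: MvnModel, em_tol: float = 1e-8) -> float:
    """Likelihood-ratio distance of a dataset from model-implied moments."""
    sat = em_saturated(np.asarray(data, dtype=float), tol=em_tol,
                       labels=list(model.labels))
    return 2.0 * (sat.loglik - mvn_loglik_missing(data, model))


@dataclass
class PlausibleValueSet:
    """M plausible-value draws of the latent reserve score per subject."""

    values: np.ndarray                  # (n_subjects, M)
    psrf: dict[str, float]
    ppp: float | None
    icc: tuple[float, tuple[float, float]] | None
    chain_summaries: pd.DataFrame

    @property
    def M(self) -> int:
        return self.values.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=1)


def draw_plausible_values(chains: GibbsChains, M: int = 30, seed: int = 0) -> PlausibleValueSet:
    """Select M stored latent vectors, equally spaced and alternating chains."""
    n_stored = chains.latent.shape[0]
    if n_stored < M:
        need = M * max(1, int(np.ceil(
            chains.n_retained * len(chains.params) / max(n_stored, 1))))
        raise ValueError(
            f"only {n_stored} stored latent draws; need >= {M} "
            f"(increase iterations to about {need} per chain or raise max_stored_latent)"
        )
    # order stored draws by (iteration, chain) so consecutive picks alternate chains
    order = np.lexsort((chains.latent_chain, chains.latent_iter))
    pick = order[np.linspace(0, n_stored - 1, M).astype(int)]
    values = chains.latent[pick].T  # (n_subjects, M)

    rates = chains_psrf(chains)
    rows = []
    for name in chains.param_names:
        stacked = chains.stacked(name)
        rows.append({
            "parameter": name,
            "mean": float(stacked.mean()),
            "sd": float(stacked.std(ddof=1)),
            "psrf": rates[name],
        })
    summary = pd.DataFrame(rows)
    icc = icc2k(values) if M >= 2 else None
    return PlausibleValueSet(
        values=values, psrf=rates, ppp=None, icc=icc, chain_summaries=summary
    )


def icc2k(values: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,k): two-way random effects, absolute agreement, mean of k ratings.

    Computed from the two-way ANOVA mean squares (rows = subjects, columns =
    imputations) with an F-based confidence interval (single-rater bounds
    stepped up by the Spearman-Brown relation).
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 2 or vals.shape[0] < 3 or vals.shape[1] < 2:
        raise ValueError("need a subjects x ratings matrix, >=3 rows and >=2 columns")
    if np.isnan(vals).any():
        raise ValueError("missing cells not supported")
    n, k = vals.shape
    grand = vals.mean()
    row_means = vals.mean(axis=1)
    col_means = vals.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((vals - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr <= 0:
        raise ValueError("zero between-subject variance: ICC undefined")

    icc_k = (msr - mse) / (msr + (msc - mse) / n)
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # Shrout-Fleiss CI for the single-rater ICC(2,1), then Spearman-Brown
    a = k * icc_1 / (n * (1.0 - icc_1)) if icc_1 < 1.0 else np.inf
    b = 1.0 + k * icc_1 * (n - 1.0) / (n * (1.0 - icc_1)) if icc_1 < 1.0 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        sb = lambda r: k * r / (1.0 + (k - 1) * r) if np.isfinite(r) else 1.0
        ci = (float(sb(lo1)), float(sb(hi1)))
    else:
        ci = (1.0, 1.0)
    return float(icc_k), ci
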