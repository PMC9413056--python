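"""Vectorized case-bootstrap refitting of the mediation model.

The case bootstrap refits every block of the structural model on each
resample.  Looping over resamples repeats thousands of small-matrix
operations in Python; this module instead carries the resampling through
*sufficient statistics*: a resample is a vector of subject counts, and
every quantity entering the likelihoods (cross-product matrices per
EF-missingness pattern, mediator-regression normal equations) is linear in
those counts, so all B resamples are evaluated together with batched
linear algebra.

The growth block's profile likelihood (4 variance parameters after GLS
concentration of the fixed effects) is maximized for all resamples at once
with a damped Newton iteration: the analytic batched gradient, a
finite-difference Hessian refreshed when progress stalls, and per-resample
step damping.  This is the same ML refit as the loop path, just computed
in parallel; equivalence is asserted in the test suite.

Only the default shared-EF-residual-variance model is supported here; the
generic per-resample loop remains the fallback.
"""

from __future__ import annotations

import numpy as np

from .effects import effect_quantities
from .mediation import (
    MediationDataset,
    _growth_patterns,
    _u_design,
    fit_growth_mediation,
    mediator_designs,
)

__all__ = ["GrowthEffectsEstimator"]


def _batched_ols(counts: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Weighted-normal-equation OLS coefficients for all resamples."""
    A = np.einsum("bn,ni,nj->bij", counts, X, X, optimize=True)
    c = np.einsum("bn,ni,n->bi", counts, X, y, optimize=True)
    q = X.shape[1]
    A = A + 1e-12 * np.eye(q)
    return np.linalg.solve(A, c[..., None])[..., 0]


class _BatchStats:
    """Per-pattern sufficient statistics for a set of resample counts."""

    def __init__(self, patterns=None, counts=None):
        self.items = []
        if patterns is None:
            return
        for pat in patterns:
            w = counts[:, pat["rows"]]                       # (B, n_p)
            U, Y, Z = pat["U"], pat["Y"], pat["Z"]
            self.items.append({
                "Z": Z,
                "k": pat["k"],
                "n_b": w.sum(axis=1),                         # (B,)
                "Suu": np.einsum("bn,ni,nj->bij", w, U, U, optimize=True),
                "T": np.einsum("bn,ni,nk->bik", w, U, Y, optimize=True),
                "Syy": np.einsum("bn,nk,nl->bkl", w, Y, Y, optimize=True),
            })

    def subset(self, idx: np.ndarray) -> "_BatchStats":
        sub = _BatchStats()
        for it in self.items:
            sub.items.append({
                "Z": it["Z"], "k": it["k"], "n_b": it["n_b"][idx],
                "Suu": it["Suu"][idx], "T": it["T"][idx], "Syy": it["Syy"][idx],
            })
        return sub


def _batched_negll_grad(phi: np.ndarray, stats: _BatchStats, p: int):
    """Batched profile -loglik and gradient over the 4 variance parameters.

    ``phi`` is (B, 4): log-Cholesky of the growth-factor covariance and the
    log shared EF residual variance.  Returns (nll (B,), grad (B,4),
    gamma (B, 2p)).
    """
    B = phi.shape[0]
    l11 = np.exp(phi[:, 0])
    l21 = phi[:, 1]
    l22 = np.exp(phi[:, 2])
    sig2 = np.exp(phi[:, 3])
    # psi = L L'
    psi = np.empty((B, 2, 2))
    psi[:, 0, 0] = l11**2
    psi[:, 0, 1] = psi[:, 1, 0] = l11 * l21
    psi[:, 1, 1] = l21**2 + l22**2
    # dpsi/dphi_a, a = 0..2
    dpsi = np.zeros((3, B, 2, 2))
    dpsi[0, :, 0, 0] = 2.0 * l11**2
    dpsi[0, :, 0, 1] = dpsi[0, :, 1, 0] = l11 * l21
    dpsi[1, :, 0, 1] = dpsi[1, :, 1, 0] = l11
    dpsi[1, :, 1, 1] = 2.0 * l21
    dpsi[2, :, 1, 1] = 2.0 * l22**2

    P2 = 2 * p
    N = np.zeros((B, P2, P2))
    rhs = np.zeros((B, P2))
    nll_acc = np.zeros(B)
    cache = []
    for it in stats.items:
        Z, k, n_b = it["Z"], it["k"], it["n_b"]
        V = np.einsum("ki,bij,lj->bkl", Z, psi, Z, optimize=True) \
            + sig2[:, None, None] * np.eye(k)
        cho = np.linalg.cholesky(V)
        logdet = 2.0 * np.log(np.einsum("bkk->bk", cho)).sum(axis=1)
        Vinv = np.linalg.inv(V)
        C = np.einsum("ki,bkl,lj->bij", Z, Vinv, Z, optimize=True)   # (B,2,2)
        N[:, :p, :p] += C[:, 0, 0, None, None] * it["Suu"]
        N[:, :p, p:] += C[:, 0, 1, None, None] * it["Suu"]
        N[:, p:, :p] += C[:, 1, 0, None, None] * it["Suu"]
        N[:, p:, p:] += C[:, 1, 1, None, None] * it["Suu"]
        P = np.einsum("ki,bkl->bil", Z, Vinv, optimize=True)          # (B,2,k)
        rhs[:, :p] += np.einsum("bpk,bk->bp", it["T"], P[:, 0, :], optimize=True)
        rhs[:, p:] += np.einsum("bpk,bk->bp", it["T"], P[:, 1, :], optimize=True)
        nll_acc += 0.5 * (n_b * (k * np.log(2.0 * np.pi)) + n_b * logdet
                          + np.einsum("bkl,bkl->b", Vinv, it["Syy"]))
        cache.append((it, Vinv))
    gamma = np.linalg.solve(N, rhs[..., None])[..., 0]
    nll = nll_acc - 0.5 * np.einsum("bp,bp->b", gamma, rhs)

    grad = np.zeros((B, 4))
    gI, gS = gamma[:, :p], gamma[:, p:]
    for it, Vinv in cache:
        Z, k, n_b = it["Z"], it["k"], it["n_b"]
        z0, z1 = Z[:, 0], Z[:, 1]
        t1 = np.einsum("bp,bpk->bk", gI, it["T"], optimize=True)
        t2 = np.einsum("bp,bpk->bk", gS, it["T"], optimize=True)
        c11 = np.einsum("bp,bpq,bq->b", gI, it["Suu"], gI, optimize=True)
        c12 = np.einsum("bp,bpq,bq->b", gI, it["Suu"], gS, optimize=True)
        c22 = np.einsum("bp,bpq,bq->b", gS, it["Suu"], gS, optimize=True)
        MtY = z0[None, :, None] * t1[:, None, :] + z1[None, :, None] * t2[:, None, :]
        MtM = (c11[:, None, None] * np.outer(z0, z0)
               + c12[:, None, None] * (np.outer(z0, z1) + np.outer(z1, z0))
               + c22[:, None, None] * np.outer(z1, z1))
        Rr = it["Syy"] - MtY - MtY.transpose(0, 2, 1) + MtM
        E = Vinv @ Rr @ Vinv
        for a in range(3):
            dV = np.einsum("ki,bij,lj->bkl", Z, dpsi[a], Z, optimize=True)
            grad[:, a] += 0.5 * (n_b * np.einsum("bkl,bkl->b", Vinv, dV)
                                 - np.einsum("bkl,bkl->b", dV, E))
        trV = np.einsum("bkk->b", Vinv)
        trE = np.einsum("bkk->b", E)
        grad[:, 3] += 0.5 * sig2 * (n_b * trV - trE)
    return nll, grad, gamma


def _batched_newton(phi0, stats, p, max_iter=25, gtol=1e-4):
    """Damped Newton maximization of the batched profile likelihood.

    Converged resamples are retired from the active set each iteration; the
    finite-difference Hessian is refreshed for stragglers.
    """
    B = phi0.shape[0]
    phi = phi0.copy()
    nll, grad, gamma = _batched_negll_grad(phi, stats, p)
    lam = np.full(B, 1e-4)

    def hessian(phi_c, stats_c, grad_c):
        h = 1e-4
        nb = phi_c.shape[0]
        H = np.empty((nb, 4, 4))
        for j in range(4):
            pj = phi_c.copy()
            pj[:, j] += h
            _, gj, _ = _batched_negll_grad(pj, stats_c, p)
            H[:, :, j] = (gj - grad_c) / h
        return 0.5 * (H + H.transpose(0, 2, 1))

    H = hessian(phi, stats, grad)
    fail_streak = np.zeros(B, dtype=int)
    for _ in range(max_iter):
        act = np.flatnonzero(np.abs(grad).max(axis=1) > gtol)
        if act.size == 0:
            break
        st = stats.subset(act)
        Hd = H[act] + lam[act, None, None] * np.eye(4)
        try:
            step = np.linalg.solve(Hd, grad[act, :, None])[..., 0]
        except np.linalg.LinAlgError:
            Hd = Hd + 1e-2 * np.eye(4)
            step = np.linalg.solve(Hd, grad[act, :, None])[..., 0]
        cand = np.clip(phi[act] - step, -12.0, 8.0)
        nll_c, grad_c, gamma_c = _batched_negll_grad(cand, st, p)
        better = nll_c <= nll[act] + 1e-12
        good = act[better]
        bad = act[~better]
        phi[good] = cand[better]
        nll[good] = nll_c[better]
        grad[good] = grad_c[better]
        gamma[good] = gamma_c[better]
        lam[good] = np.maximum(lam[good] * 0.3, 1e-6)
        fail_streak[good] = 0
        lam[bad] *= 10.0
        fail_streak[bad] += 1
        refresh = act[(fail_streak[act] >= 2)]
        if refresh.size:
            H[refresh] = hessian(phi[refresh], stats.subset(refresh),
                                 grad[refresh])
            fail_streak[refresh] = 0
    converged = np.abs(grad).max(axis=1) <= 100 * gtol
    return phi, gamma, converged


class GrowthEffectsEstimator:
    """Fit-and-extract map for :func:`atnreserve.effects.bc_bootstrap`.

    Called on a dataset it refits all blocks and returns the effect
    quantities; ``batch`` performs the identical refit for every resample
    at once via batched sufficient statistics.
    """

    def __init__(self, w_grid, warm_phi=None):
        self.w_grid = tuple(float(w) for w in np.atleast_1d(w_grid))
        self.warm_phi = warm_phi

    def __call__(self, ds: MediationDataset) -> dict[str, float]:
        fit = fit_growth_mediation(ds, start_phi=self.warm_phi, max_restarts=0)
        return {k: float(v) for k, v in
                effect_quantities(fit.coef, self.w_grid).items()}

    def batch(self, ds: MediationDataset, idx_all: np.ndarray) -> dict[str, np.ndarray]:
        spec = ds.spec
        if spec.ef_residual != "shared":
            raise NotImplementedError("batch path supports shared EF residuals only")
        B, n = idx_all.shape
        counts = np.zeros((B, n))
        for b in range(B):
            counts[b] = np.bincount(idx_all[b], minlength=n)

        cols1, names1, cols2, names2 = mediator_designs(ds)
        X1 = np.column_stack(cols1)
        X2 = np.column_stack(cols2)
        coef1 = _batched_ols(counts, X1, ds.m1)
        coef2 = _batched_ols(counts, X2, ds.m2)

        U, names_I, names_S = _u_design(ds)
        p = U.shape[1]
        loadings = np.asarray(spec.slope_loadings, dtype=float)
        patterns = _growth_patterns(U, ds.ef, loadings)
        stats = _BatchStats(patterns, counts)

        if self.warm_phi is not None:
            phi0 = np.tile(np.asarray(self.warm_phi, dtype=float), (B, 1))
        else:
            fit0 = fit_growth_mediation(ds)
            phi0 = np.tile(fit0.phi, (B, 1))
        phi, gamma, converged = _batched_newton(phi0, stats, p)

        coefs: dict[str, np.ndarray] = {}
        for j, nm in enumerate(names1):
            coefs[nm] = coef1[:, j]
        for j, nm in enumerate(names2):
            coefs[nm] = coef2[:, j]
        for j, nm in enumerate(names_I):
            coefs[nm] = gamma[:, j]
        for j, nm in enumerate(names_S):
            coefs[nm] = gamma[:, p + j]
        out = {k: np.asarray(v, dtype=float)
               for k, v in effect_quantities(coefs, self.w_grid).items()}
        bad = ~converged
        if bad.any():
            for k in out:
                out[k][bad] = np.nan
        return out
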