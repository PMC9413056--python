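"""Tests of the moderated mediation estimator: design construction, OLS and
brute-force/Mixed-model oracles for the growth block, likelihood algebra,
fit statistics and model-implied trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import atnreserve as a
from atnreserve.mediation import (
    MediationFit,
    MediationSpec,
    build_design,
    fit_growth_mediation,
    mediator_designs,
    model_fit_indices,
    predict_trajectories,
    _u_design,
)


def _make_fit(coefs: dict, **kw) -> MediationFit:
    """Lightweight fit object with hand-set coefficients."""
    return MediationFit(
        coefficients=pd.Series(coefs, dtype=float),
        ses=pd.Series({k: 0.1 for k in coefs}),
        psi_eta=np.eye(2) * 0.1,
        theta_ef=np.array([0.1]),
        logliks={}, n_used=100, converged=True,
        phi=np.zeros(4), nparams={}, **kw,
    )


class TestBuildDesign:
    def test_products(self, mediation_dataset):
        ds = mediation_dataset
        assert np.allclose(ds.xw, ds.x * ds.w)
        assert np.allclose(ds.m1w, ds.m1 * ds.w)

    def test_zero_moderator_zeroes_products(self, small_cohort):
        tab = small_cohort.copy()
        tab.attrs = dict(small_cohort.attrs)
        tab["memr"] = 0.0
        ds = build_design(tab, MediationSpec())
        assert np.all(ds.xw == 0) and np.all(ds.m2w == 0)

    def test_complete_case_restriction_matches_fraction(self, default_truth):
        cc = a.CohortConfig(n_subjects=1_000, seed=31,
                            complete_biomarker_fraction=0.33)
        raw = a.apply_missingness(a.generate_cohort(cc, default_truth), cc)
        pre = a.preprocess(raw)
        ds = build_design(pre, MediationSpec(w_col="true_memr"))
        assert ds.n == round(0.33 * 1_000)

    def test_empty_sample_rejected(self, small_cohort):
        tab = small_cohort.copy()
        tab.attrs = dict(small_cohort.attrs)
        tab["memr"] = np.nan
        with pytest.raises(ValueError, match="no subjects"):
            build_design(tab, MediationSpec())


class TestMediatorBlocks:
    def test_ols_closed_form(self, mediation_dataset, mediation_fit):
        ds, fit = mediation_dataset, mediation_fit
        cols1, names1, cols2, names2 = mediator_designs(ds)
        for cols, names, y in ((cols1, names1, ds.m1), (cols2, names2, ds.m2)):
            X = np.column_stack(cols)
            ols = np.linalg.lstsq(X, y, rcond=None)[0]
            ours = np.array([fit.coef(n) for n in names])
            assert np.allclose(ours, ols, atol=1e-8)


class TestGrowthBlock:
    def test_matches_brute_force_joint_likelihood(self, default_truth):
        """Complete balanced EF: profile-GLS estimates equal direct numerical
        maximization of the joint multivariate-normal likelihood."""
        cc = a.CohortConfig(n_subjects=150, seed=33, complete_biomarker_fraction=1.0,
                            dropout_intercept=-40.0)
        raw = a.apply_missingness(a.generate_cohort(cc, default_truth), cc)
        pre = a.preprocess(raw, standardize_ef=False)
        ds = build_design(pre, MediationSpec(w_col="true_memr"))
        fit = fit_growth_mediation(ds)

        U, names_I, names_S = _u_design(ds)
        p = U.shape[1]
        lam = np.arange(8) - 3.0
        Z = np.column_stack([np.ones(8), lam])
        Y = ds.ef

        def negll(theta):
            gI, gS = theta[:p], theta[p:2 * p]
            L = np.array([[np.exp(theta[2 * p]), 0.0],
                          [theta[2 * p + 1], np.exp(theta[2 * p + 2])]])
            V = Z @ (L @ L.T) @ Z.T + np.exp(theta[2 * p + 3]) * np.eye(8)
            mean = np.outer(U @ gI, Z[:, 0]) + np.outer(U @ gS, Z[:, 1])
            return -stats.multivariate_normal.logpdf(Y - mean,
                                                     np.zeros(8), V).sum()

        # independent maximization from a neutral start
        x0 = np.concatenate([np.zeros(2 * p), [np.log(0.5), 0.0,
                                               np.log(0.1), np.log(0.4)]])
        res = optimize.minimize(negll, x0, method="L-BFGS-B",
                                options={"maxiter": 20000, "ftol": 1e-15,
                                         "gtol": 1e-10, "maxfun": 100000})
        res = optimize.minimize(negll, res.x, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 50000, "maxfev": 50000})
        ours = np.array([fit.coef(n) for n in names_I + names_S])
        assert np.allclose(ours, res.x[:2 * p], atol=1e-6)
        assert -negll(np.concatenate([ours, fit.phi])) == pytest.approx(
            fit.logliks["growth"], abs=1e-6
        )

    def test_matches_mixedlm_under_dropout(self, mediation_dataset, mediation_fit):
        """Independent cross-check: random intercept+slope mixed model (ML)
        on the long-format data reproduces the FIML growth estimates."""
        smf = pytest.importorskip("statsmodels.formula.api")
        import statsmodels.api as sm
        ds, fit = mediation_dataset, mediation_fit
        U, names_I, names_S = _u_design(ds)
        rows = []
        for i in range(ds.n):
            for t in range(8):
                if np.isnan(ds.ef[i, t]):
                    continue
                rows.append(np.concatenate([[ds.ef[i, t], t - 3.0], U[i]]))
        cols = ["y", "time"] + [f"u{j}" for j in range(U.shape[1])]
        long = pd.DataFrame(rows, columns=cols)
        long["group"] = np.repeat(np.arange(ds.n),
                                  (~np.isnan(ds.ef)).sum(axis=1))
        exog_cols = [f"u{j}" for j in range(U.shape[1])] \
            + [f"u{j}:time" for j in range(U.shape[1])]
        exog = np.column_stack(
            [long[f"u{j}"] for j in range(U.shape[1])]
            + [long[f"u{j}"] * long["time"] for j in range(U.shape[1])]
        )
        md = sm.MixedLM(long["y"], exog, groups=long["group"],
                        exog_re=np.column_stack([np.ones(len(long)),
                                                 long["time"]]))
        mres = md.fit(reml=False)
        assert fit.logliks["growth"] == pytest.approx(mres.llf, abs=1e-5)
        ours = np.array([fit.coef(n) for n in names_I + names_S])
        assert np.allclose(ours, mres.fe_params, atol=2e-4)
        assert np.allclose(fit.psi_eta, mres.cov_re.to_numpy(), atol=1e-4)
        assert fit.theta_ef[0] == pytest.approx(mres.scale, abs=1e-5)

    def test_total_loglik_is_direct_joint_conditional_density(
        self, mediation_dataset, mediation_fit
    ):
        """Block separability: the summed block log-likelihoods equal the
        directly evaluated recursive conditional density."""
        ds, fit = mediation_dataset, mediation_fit
        cols1, names1, cols2, names2 = mediator_designs(ds)
        ll = 0.0
        for cols, names, y in ((cols1, names1, ds.m1), (cols2, names2, ds.m2)):
            X = np.column_stack(cols)
            coefs = np.array([fit.coef(n) for n in names])
            r = y - X @ coefs
            s2 = float(r @ r) / ds.n
            ll += stats.norm.logpdf(r, 0.0, np.sqrt(s2)).sum()
        U, names_I, names_S = _u_design(ds)
        gI = np.array([fit.coef(n) for n in names_I])
        gS = np.array([fit.coef(n) for n in names_S])
        lam = np.arange(8) - 3.0
        for i in range(ds.n):
            obs = ~np.isnan(ds.ef[i])
            if not obs.any():
                continue
            Zi = np.column_stack([np.ones(obs.sum()), lam[obs]])
            Vi = Zi @ fit.psi_eta @ Zi.T + fit.theta_ef[0] * np.eye(int(obs.sum()))
            mean = Zi @ np.array([U[i] @ gI, U[i] @ gS])
            ll += stats.multivariate_normal.logpdf(ds.ef[i, obs], mean, Vi)
        assert ll == pytest.approx(fit.logliks["total"], abs=1e-6)

    def test_null_interactions_estimated_near_zero(self):
        truth = a.TrueParams(a2w=0.0)
        inter = ["a1w", "a2w", "d21w", "b1w_I", "b1w_S",
                 "b2w_I", "b2w_S", "cw_I", "cw_S"]
        ests = []
        for rep in range(30):
            cc = a.CohortConfig(n_subjects=332, seed=4000 + rep,
                                complete_biomarker_fraction=1.0)
            pre = a.preprocess(a.apply_missingness(
                a.generate_cohort(cc, truth), cc), standardize_ef=False)
            fit = fit_growth_mediation(build_design(
                pre, MediationSpec(w_col="true_memr")))
            ests.append([fit.coef(n) for n in inter])
        ests = np.array(ests)
        mc_se = ests.std(axis=0) / np.sqrt(len(ests))
        assert np.all(np.abs(ests.mean(axis=0)) < 3 * mc_se + 1e-3)

    def test_centering_equivariance_of_slope_loadings(self, mediation_dataset):
        """Moving the intercept from T3 to T0 shifts intercept-equation
        coefficients by -3 x slope coefficients and leaves slopes alone."""
        ds = mediation_dataset
        fit3 = fit_growth_mediation(ds)
        spec0 = MediationSpec(w_col="true_memr",
                              slope_loadings=tuple(float(t) for t in range(8)))
        ds0 = build_design(
            _as_table(ds), spec0
        )
        fit0 = fit_growth_mediation(ds0)
        U, names_I, names_S = _u_design(ds)
        for nI, nS in zip(names_I, names_S):
            assert fit0.coef(nS) == pytest.approx(fit3.coef(nS), abs=1e-6)
            assert fit0.coef(nI) == pytest.approx(
                fit3.coef(nI) - 3.0 * fit3.coef(nS), abs=1e-6
            )


def _as_table(ds):
    """Rebuild a minimal table from a design (test helper)."""
    tab = pd.DataFrame({
        "abeta_ratio": ds.x, "true_memr": ds.w,
        "ptau_t1": ds.m1, "fdg_t2": ds.m2,
        "age_c": ds.cov[:, 0], "sex": ds.cov[:, 1], "educ_c": ds.cov[:, 2],
    })
    for t in range(8):
        tab[f"ef_t{t}"] = ds.ef[:, t]
    return tab


class TestFitIndicesForMediation:
    def test_correctly_specified_model_fits_well(self, default_truth):
        good = 0
        for rep in range(5):
            cc = a.CohortConfig(n_subjects=800, seed=5000 + rep,
                                complete_biomarker_fraction=1.0)
            pre = a.preprocess(a.apply_missingness(
                a.generate_cohort(cc, default_truth), cc), standardize_ef=False)
            ds = build_design(pre, MediationSpec(w_col="true_memr"))
            fit = fit_growth_mediation(ds)
            idx = model_fit_indices(fit, ds)
            good += idx.rmsea < 0.05
        assert good >= 4

    def test_quadratic_time_trend_is_flagged(self, default_truth):
        flagged = 0
        for rep in range(3):
            cc = a.CohortConfig(n_subjects=800, seed=6000 + rep,
                                complete_biomarker_fraction=1.0)
            raw = a.generate_cohort(cc, default_truth)
            for t in range(8):
                raw[f"ef_t{t}"] = raw[f"ef_t{t}"] + 0.12 * (t - 3.0) ** 2
            raw = a.apply_missingness(raw, cc)
            pre = a.preprocess(raw, standardize_ef=False)
            ds = build_design(pre, MediationSpec(w_col="true_memr"))
            fit = fit_growth_mediation(ds)
            idx = model_fit_indices(fit, ds)
            flagged += idx.rmsea > 0.08
        assert flagged >= 2


class TestPredictTrajectories:
    def test_all_paths_zero_gives_flat_identical_curves(self):
        fit = _make_fit({"intercept_const": 0.7, "slope_const": 0.0})
        out = predict_trajectories(fit, x_levels=(-1, 0, 1), w_levels=(-1, 0, 1))
        assert np.allclose(out["ef"], 0.7)

    def test_hand_algebra_for_moderated_fdg_path(self):
        # a2 = 0.3, a2w = -0.15, d21 = 0, b2_I = 0.4, g_fdg = 0
        fit = _make_fit({"a2": 0.3, "a2w": -0.15, "b2_I": 0.4})
        out = predict_trajectories(fit, x_levels=(1.0,), w_levels=(-1.0, 1.0))
        m2 = out.drop_duplicates(["x", "w"]).set_index("w")["m2"]
        assert m2[1.0] - m2[-1.0] == pytest.approx(2 * (-0.15), abs=1e-12)

    def test_extrapolation_warning(self):
        fit = _make_fit({"intercept_const": 0.0})
        with pytest.warns(RuntimeWarning, match="extrapolation"):
            predict_trajectories(fit, x_levels=(9.0,), w_levels=(0.0,))

    def test_reserve_ordering_at_high_pathology(self, mediation_fit):
        """Higher reserve predicts better EF at T3 when amyloid pathology is
        severe (low amyloid ratio)."""
        w_sd = mediation_fit.w_sd
        out = predict_trajectories(mediation_fit, x_levels=(-1.0, 1.0),
                                   w_levels=(-w_sd, w_sd))
        at = out[out["t"] == 3].set_index(["x", "w"])["ef"]
        gap_high_path = at[(-1.0, w_sd)] - at[(-1.0, -w_sd)]
        assert gap_high_path > 0
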