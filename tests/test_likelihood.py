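"""Unit tests for the shared multivariate-normal likelihood machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from atnreserve.likelihood import (
    DegenerateScaleError,
    MvnModel,
    SaturatedModelError,
    UnidentifiableVariableError,
    em_saturated,
    fit_indices,
    mvn_loglik_missing,
    observed_info_se,
    srmr,
)


def _random_model(rng, p):
    A = rng.standard_normal((p, p))
    cov = A @ A.T + p * np.eye(p)
    return MvnModel(rng.standard_normal(p), cov, tuple(f"v{j}" for j in range(p)))


class TestMvnLoglik:
    def test_standard_normal_density_at_zero(self):
        model = MvnModel(np.zeros(1), np.eye(1), ("x",))
        assert mvn_loglik_missing(np.array([[0.0]]), model) == pytest.approx(
            -0.5 * np.log(2 * np.pi)
        )

    def test_all_missing_row_contributes_zero(self):
        rng = np.random.default_rng(0)
        model = _random_model(rng, 3)
        data = rng.standard_normal((4, 3))
        with_empty = np.vstack([data, np.full((1, 3), np.nan)])
        assert mvn_loglik_missing(with_empty, model) == pytest.approx(
            mvn_loglik_missing(data, model), abs=1e-12
        )

    def test_matches_per_row_marginal_densities(self):
        """Brute-force oracle: explicit sub-matrix extraction per row."""
        rng = np.random.default_rng(1)
        model = _random_model(rng, 2)
        data = rng.standard_normal((3, 2))
        data[1, 0] = np.nan
        expected = 0.0
        for row in data:
            obs = ~np.isnan(row)
            expected += stats.multivariate_normal.logpdf(
                row[obs], model.mean[obs], model.cov[np.ix_(obs, obs)]
            )
        assert mvn_loglik_missing(data, model) == pytest.approx(expected, abs=1e-10)

    def test_complete_data_equals_standard_mvn_density(self):
        rng = np.random.default_rng(2)
        model = _random_model(rng, 4)
        data = rng.standard_normal((20, 4))
        expected = stats.multivariate_normal.logpdf(data, model.mean, model.cov).sum()
        assert mvn_loglik_missing(data, model) == pytest.approx(expected, abs=1e-10)

    def test_singular_subblock_raises(self):
        model = MvnModel(np.zeros(2), np.array([[1.0, 1.0], [1.0, 1.0]]), ("a", "b"))
        data = np.array([[0.1, np.nan]])  # 1x1 block fine; full block singular
        with pytest.raises(Exception):
            mvn_loglik_missing(np.array([[0.1, 0.2]]), model)
        # observed sub-block [a] alone is invertible
        assert np.isfinite(mvn_loglik_missing(data, model))


class TestEmSaturated:
    def test_complete_data_closed_form(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((25, 3)) @ np.diag([1.0, 2.0, 0.5])
        res = em_saturated(data)
        assert np.allclose(res.model.mean, data.mean(axis=0), atol=1e-10)
        assert np.allclose(res.model.cov, np.cov(data, rowvar=False, bias=True),
                           atol=1e-10)

    def test_matches_direct_likelihood_maximization(self):
        """Five-row bivariate toy with one missing cell vs a generic optimizer."""
        data = np.array([
            [0.2, 1.1],
            [-0.5, 0.3],
            [1.4, np.nan],
            [0.9, -0.2],
            [-1.1, 0.8],
        ])
        res = em_saturated(data, tol=1e-13, max_iter=5000)

        def negll(theta):
            mu = theta[:2]
            L = np.array([[np.exp(theta[2]), 0.0], [theta[3], np.exp(theta[4])]])
            model = MvnModel(mu, L @ L.T, ("a", "b"))
            return -mvn_loglik_missing(data, model)

        x0 = np.array([0.0, 0.0, 0.0, 0.0, 0.0])
        opt = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 20000, "maxfev": 20000})
        L = np.array([[np.exp(opt.x[2]), 0.0], [opt.x[3], np.exp(opt.x[4])]])
        cov_opt = L @ L.T
        assert np.allclose(res.model.mean, opt.x[:2], atol=1e-6)
        assert np.allclose(res.model.cov, cov_opt, atol=1e-6)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((10, 2))
        data[rng.random((10, 2)) < 0.2] = np.nan
        r1 = em_saturated(data)
        r2 = em_saturated(np.vstack([data, data]))
        assert np.allclose(r1.model.mean, r2.model.mean, atol=1e-6)
        assert np.allclose(r1.model.cov, r2.model.cov, atol=1e-6)

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((40, 4))
        data[rng.random((40, 4)) < 0.3] = np.nan
        res = em_saturated(data)
        diffs = np.diff(res.loglik_path)
        assert np.all(diffs >= -1e-8)

    def test_never_observed_variable_raises(self):
        data = np.array([[1.0, np.nan], [2.0, np.nan], [0.5, np.nan]])
        with pytest.raises(UnidentifiableVariableError):
            em_saturated(data)


class TestFitIndices:
    def test_perfect_fit(self):
        f = fit_indices(-100.0, 5, -100.0, 10, -150.0, 2, n=50)
        assert f.chisq == 0.0 and f.rmsea == 0.0 and f.cfi == 1.0

    def test_rmsea_hand_formula(self):
        # chisq 50, df 10, n 101 -> sqrt(40 / (10 * 100)) = 0.2
        f = fit_indices(-125.0, 0, -100.0, 10, -200.0, 0, n=101)
        assert f.chisq == pytest.approx(50.0)
        assert f.rmsea == pytest.approx(np.sqrt(40.0 / 1000.0))
        lo, hi = f.rmsea_ci90
        assert lo <= f.rmsea <= hi

    def test_cfi_hand_formula(self):
        # chisq 50 df 10; baseline chisq 200 df 15 -> 1 - 40/185
        f = fit_indices(-125.0, 5, -100.0, 15, -200.0, 0, n=101)
        assert f.df == 10 and f.chisq == pytest.approx(50.0)
        base_chisq = 2 * (-100.0 - (-200.0))
        assert base_chisq == 200.0 and f.df == 10
        assert f.cfi == pytest.approx(1.0 - 40.0 / 185.0)

    def test_saturated_model_raises(self):
        with pytest.raises(SaturatedModelError):
            fit_indices(-100.0, 10, -100.0, 10, -150.0, 2, n=50)

    @given(shift=st.floats(-1e4, 1e4))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_common_loglik_shift(self, shift):
        f0 = fit_indices(-120.0, 5, -100.0, 12, -180.0, 2, n=80)
        f1 = fit_indices(-120.0 + shift, 5, -100.0 + shift, 12,
                         -180.0 + shift, 2, n=80)
        assert f1.rmsea == pytest.approx(f0.rmsea, abs=1e-10)
        assert f1.cfi == pytest.approx(f0.cfi, abs=1e-10)


class TestSrmr:
    def test_identical_moments_zero(self):
        rng = np.random.default_rng(6)
        m = _random_model(rng, 3)
        assert srmr(m, m) == 0.0

    def test_hand_computation_two_variables(self):
        obs = MvnModel(np.zeros(2), np.array([[1.0, 0.5], [0.5, 1.0]]), ("a", "b"))
        imp = MvnModel(np.zeros(2), np.eye(2), ("a", "b"))
        assert srmr(obs, imp) == pytest.approx(np.sqrt(0.25 / 3.0))

    @given(s1=st.floats(0.1, 10.0), s2=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_common_rescaling(self, s1, s2):
        obs = MvnModel(np.zeros(2), np.array([[1.0, 0.5], [0.5, 2.0]]), ("a", "b"))
        imp = MvnModel(np.zeros(2), np.array([[1.1, 0.2], [0.2, 1.8]]), ("a", "b"))
        D = np.diag([s1, s2])
        obs2 = MvnModel(np.zeros(2), D @ obs.cov @ D, ("a", "b"))
        imp2 = MvnModel(np.zeros(2), D @ imp.cov @ D, ("a", "b"))
        assert srmr(obs2, imp2) == pytest.approx(srmr(obs, imp), rel=1e-9)

    def test_zero_variance_raises(self):
        obs = MvnModel(np.zeros(2), np.diag([1.0, 0.0]), ("a", "b"))
        with pytest.raises(DegenerateScaleError):
            srmr(obs, obs)


class TestObservedInfoSe:
    def test_iid_normal_mean_closed_form(self):
        rng = np.random.default_rng(7)
        sigma, n = 1.7, 60
        x = rng.normal(2.0, sigma, n)

        def ll(theta):
            return float(-0.5 * ((x - theta[0]) ** 2).sum() / sigma**2)

        se = observed_info_se(ll, np.array([x.mean()]))
        assert se[0] == pytest.approx(sigma / np.sqrt(n), abs=1e-6)

    def test_linear_regression_closed_form(self):
        rng = np.random.default_rng(8)
        n = 80
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = np.array([1.0, -0.5])
        sigma = 0.8
        y = X @ beta + rng.normal(0, sigma, n)
        bhat = np.linalg.lstsq(X, y, rcond=None)[0]

        def ll(t):
            return float(-0.5 * ((y - X @ t) ** 2).sum() / sigma**2)

        se = observed_info_se(ll, bhat)
        expected = np.sqrt(np.diag(np.linalg.inv(X.T @ X) * sigma**2))
        assert np.allclose(se, expected, atol=1e-5)

    def test_flat_direction_gets_missing_flag(self):
        x = np.array([0.3, -0.4, 1.2])

        def ll(t):
            # duplicated parameter: only the sum t0 + t1 matters
            return float(-0.5 * ((x - (t[0] + t[1])) ** 2).sum())

        se = observed_info_se(ll, np.array([x.mean() / 2, x.mean() / 2]))
        assert np.isnan(se).all()
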