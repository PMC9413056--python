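"""Tests of effect algebra (conditional indirect effects, IMM), the
bias-corrected bootstrap and Rubin's-rules pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import atnreserve as a
from atnreserve.effects import (
    bc_bootstrap,
    bc_interval,
    effect_quantities,
    imm_value,
    index_of_moderated_mediation,
    indirect_effects,
    pool_rubin,
    run_mi_inference,
)
from atnreserve.mediation import MediationSpec
from tests.test_mediation import _make_fit

COEF_NAMES = [
    "a1", "a2", "d21", "b1_I", "b1_S", "b2_I", "b2_S", "c_I", "c_S",
    "a1w", "a2w", "d21w", "b1w_I", "b1w_S", "b2w_I", "b2w_S", "cw_I", "cw_S",
]

coef_dicts = st.fixed_dictionaries({
    k: st.floats(-1.0, 1.0, allow_nan=False) for k in COEF_NAMES
})


class TestIndirectEffects:
    def test_constant_across_w_without_interactions(self):
        fit = _make_fit({"a1": 0.3, "d21": -0.2, "b2_I": 0.4, "c_I": 0.1,
                         "b1_I": -0.1, "a2": 0.2})
        tab = indirect_effects(fit, w_grid=(-2.0, 0.0, 2.0)).table
        for col in ("direct", "b_at", "b_atn", "b_an", "total"):
            for outcome in ("I", "S"):
                sub = tab[tab["outcome"] == outcome][col]
                assert sub.nunique() == 1

    def test_two_factor_product(self):
        fit = _make_fit({"a2": 0.3, "a2w": -0.1, "b2_I": 0.5})
        tab = indirect_effects(fit, w_grid=(1.0,)).table
        row = tab[(tab["outcome"] == "I")].iloc[0]
        assert row["b_an"] == pytest.approx((0.3 - 0.1) * 0.5)

    @given(coefs=coef_dicts, w=st.floats(-2, 2, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_total_equals_reduced_form_derivative(self, coefs, w):
        """Substituting the mediators out, the total effect at w equals the
        derivative of the reduced-form EF equation with respect to X."""
        fit = _make_fit(coefs)
        tab = indirect_effects(fit, w_grid=(w,)).table

        def implied_I(x):
            m1 = coefs["a1"] * x + coefs["a1w"] * x * w
            m2 = (coefs["a2"] * x + coefs["d21"] * m1
                  + coefs["a2w"] * x * w + coefs["d21w"] * m1 * w)
            return (coefs["c_I"] * x + coefs["b1_I"] * m1 + coefs["b2_I"] * m2
                    + coefs["cw_I"] * x * w + coefs["b1w_I"] * m1 * w
                    + coefs["b2w_I"] * m2 * w)

        total = implied_I(1.0) - implied_I(0.0)   # linear in x: exact derivative
        row = tab[tab["outcome"] == "I"].iloc[0]
        assert row["total"] == pytest.approx(total, abs=1e-10)

    @given(coefs=coef_dicts, w=st.floats(-2, 2, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_effect_decomposition_identity(self, coefs, w):
        fit = _make_fit(coefs)
        tab = indirect_effects(fit, w_grid=(w,)).table
        for _, row in tab.iterrows():
            assert row["total"] == pytest.approx(
                row["direct"] + row["b_at"] + row["b_atn"] + row["b_an"],
                abs=1e-10,
            )


class TestImm:
    def test_single_moderated_path_is_classic_product(self):
        fit = _make_fit({"a2": 0.3, "a2w": -0.1, "b2_I": 0.5})
        for w in (-1.0, 0.0, 2.5):
            assert index_of_moderated_mediation(fit, "AN", "I", w) == \
                pytest.approx(-0.1 * 0.5)

    def test_all_interactions_zero_gives_zero(self):
        fit = _make_fit({"a1": 0.3, "a2": 0.2, "d21": -0.4,
                         "b1_I": 0.1, "b2_I": 0.5})
        for pathway in ("AT", "ATN", "AN"):
            assert index_of_moderated_mediation(fit, pathway, "I") == 0.0

    @given(coefs=coef_dicts, w=st.floats(-2, 2, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_matches_numerical_derivative(self, coefs, w):
        fit = _make_fit(coefs)
        h = 1e-6
        for pathway, col in (("AT", "b_at"), ("ATN", "b_atn"), ("AN", "b_an")):
            up = indirect_effects(fit, w_grid=(w + h,)).table
            dn = indirect_effects(fit, w_grid=(w - h,)).table
            num = (up[up["outcome"] == "I"][col].iloc[0]
                   - dn[dn["outcome"] == "I"][col].iloc[0]) / (2 * h)
            assert index_of_moderated_mediation(fit, pathway, "I", w) == \
                pytest.approx(num, abs=1e-6)

    def test_unit_step_contrast_when_single_path_moderated(self):
        fit = _make_fit({"a2": 0.3, "a2w": -0.1, "b2_I": 0.5})
        e0 = indirect_effects(fit, w_grid=(0.0,)).table
        e1 = indirect_effects(fit, w_grid=(1.0,)).table
        step = (e1[e1["outcome"] == "I"]["b_an"].iloc[0]
                - e0[e0["outcome"] == "I"]["b_an"].iloc[0])
        assert step == pytest.approx(index_of_moderated_mediation(fit, "AN", "I"))

    def test_unknown_pathway_rejected(self):
        fit = _make_fit({"a1": 0.1})
        with pytest.raises(ValueError):
            index_of_moderated_mediation(fit, "XY", "I")


class _ArrayDataset:
    """Minimal subject-resamplable dataset for generic bootstrap tests."""

    def __init__(self, x):
        self.x = np.asarray(x, dtype=float)

    @property
    def n(self):
        return self.x.size

    def take(self, idx):
        return _ArrayDataset(self.x[idx])


class TestBcBootstrap:
    def test_constant_estimator_collapses_interval(self):
        ds = _ArrayDataset(np.arange(30.0))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            ci = bc_bootstrap(ds, lambda d: {"c": 5.0}, B=120, seed=0)
        assert (ci["c"].lo, ci["c"].hi) == (5.0, 5.0)

    def test_reduces_to_percentile_when_unbiased(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal(999)
        theta_hat = float(np.median(draws))   # exactly the central draw
        lo, hi, z0 = bc_interval(draws, theta_hat)
        assert z0 == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(np.quantile(draws, 0.025))
        assert hi == pytest.approx(np.quantile(draws, 0.975))

    def test_coverage_for_normal_mean(self):
        """Empirical 95% coverage of the BC interval for a sample mean."""
        rng = np.random.default_rng(2)
        n, B, reps = 200, 500, 200
        cover = 0
        for _ in range(reps):
            x = rng.normal(0.3, 1.0, n)
            ds = _ArrayDataset(x)
            ci = bc_bootstrap(ds, lambda d: {"m": float(d.x.mean())},
                              B=B, seed=int(rng.integers(2**31)))
            cover += ci["m"].lo <= 0.3 <= ci["m"].hi
        assert cover / reps == pytest.approx(0.95, abs=0.03)

    def test_failing_estimator_raises_above_threshold(self):
        ds = _ArrayDataset(np.arange(20.0))

        def estimator(d):
            if d.x[0] != ds.x[0]:       # fails on almost every resample
                raise RuntimeError("boom")
            return {"m": 0.0}

        with pytest.raises(RuntimeError, match="resamples failed"):
            bc_bootstrap(ds, estimator, B=100, seed=3)

    def test_small_B_rejected(self):
        with pytest.raises(ValueError):
            bc_bootstrap(_ArrayDataset(np.arange(5.0)),
                         lambda d: {"m": 0.0}, B=50)


class TestPoolRubin:
    def test_worked_example(self):
        pooled = pool_rubin(np.array([[1.0], [3.0]]), np.array([[1.0], [1.0]]))
        p = pooled[0]
        assert p.qbar == 2.0 and p.b == 2.0 and p.ubar == 1.0
        assert p.t == pytest.approx(1.0 + 1.5 * 2.0)
        assert p.se == pytest.approx(2.0)

    def test_identical_imputations_have_no_between_variance(self):
        est = np.tile([[0.5, -1.0]], (10, 1))
        ses = np.tile([[0.2, 0.3]], (10, 1))
        pooled = pool_rubin(est, ses)
        assert pooled[0].b == 0.0
        assert pooled[0].se == pytest.approx(0.2)
        assert pooled[1].se == pytest.approx(0.3)

    def test_total_variance_consistency_large_M(self):
        rng = np.random.default_rng(4)
        sigma_b, ubar = 0.3, 0.25
        M = 4000
        est = rng.normal(1.0, sigma_b, (M, 1))
        ses = np.full((M, 1), np.sqrt(ubar))
        p = pool_rubin(est, ses)[0]
        assert p.t == pytest.approx(ubar + sigma_b**2, rel=0.1)

    @given(st.integers(2, 20), st.floats(0.01, 2.0), st.floats(0.0, 2.0))
    @settings(max_examples=40, deadline=None)
    def test_pooled_variance_never_below_within(self, M, se, spread):
        est = np.linspace(0.0, spread, M)[:, None]
        ses = np.full((M, 1), se)
        p = pool_rubin(est, ses)[0]
        assert p.t >= p.ubar - 1e-12

    def test_single_imputation_rejected(self):
        with pytest.raises(ValueError, match="M < 2"):
            pool_rubin(np.array([[1.0]]), np.array([[1.0]]))

    def test_barnard_rubin_df_below_classic(self):
        est = np.array([[1.0], [1.4], [0.7]])
        ses = np.array([[0.5], [0.5], [0.5]])
        classic = pool_rubin(est, ses)[0].df
        small = pool_rubin(est, ses, nu_com=30)[0].df
        assert small < classic
        assert small < 30


class TestRunMiInference:
    def test_identical_columns_match_single_fit(self, default_truth):
        cc = a.CohortConfig(n_subjects=250, seed=44, complete_biomarker_fraction=1.0)
        pre = a.preprocess(a.apply_missingness(
            a.generate_cohort(cc, default_truth), cc), standardize_ef=False)
        spec = MediationSpec(w_col="memr")
        w = pre["true_memr"].to_numpy()
        values = np.tile(w[:, None], (1, 4))
        res = run_mi_inference(values, pre, spec, B=120, seed=1,
                               w_grid=(0.0,))
        assert np.allclose(res.pooled["between_var"], 0.0, atol=1e-16)
        ds = a.build_design(
            pre.assign(memr=w), spec
        )
        single = a.fit_growth_mediation(ds)
        for name in ("a1", "a2w", "b2_I", "g_I"):
            row = res.pooled[res.pooled["coefficient"] == name].iloc[0]
            assert row["estimate"] == pytest.approx(single.coef(name), abs=1e-8)

    def test_misaligned_values_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="row-aligned"):
            run_mi_inference(np.zeros((10, 3)), small_cohort, MediationSpec())


class TestBatchedBootstrapRefit:
    def test_batch_path_equals_per_resample_refits(self, mediation_dataset,
                                                   mediation_fit):
        """The vectorized bootstrap engine performs the identical ML refit
        as looping fit_growth_mediation over resamples."""
        from atnreserve._fastboot import GrowthEffectsEstimator
        ds = mediation_dataset
        est = GrowthEffectsEstimator(w_grid=(-0.5, 0.0, 0.5),
                                     warm_phi=mediation_fit.phi)
        rng = np.random.default_rng(9)
        idx_all = rng.integers(0, ds.n, size=(15, ds.n))
        batched = est.batch(ds, idx_all)
        for b in range(15):
            loop = est(ds.take(idx_all[b]))
            for k, v in loop.items():
                assert batched[k][b] == pytest.approx(v, abs=1e-6), k
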