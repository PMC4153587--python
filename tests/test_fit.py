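"""Weighted least squares, AIC machinery, lag-depth profiling and inference."""

import numpy as np
import pandas as pd
import pytest

import aphidlag as al
from aphidlag.fit import fit_table


def random_problem(rng, n=40, p=4):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta = rng.normal(size=p)
    w = rng.uniform(0.5, 5.0, n)
    y = X @ beta + rng.normal(0, 1, n) / np.sqrt(w)
    return y, X, w


class TestWlsFit:
    def test_exact_fit_has_zero_residuals_and_unit_r2(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = 2.0 + 3.0 * np.arange(10.0)
        res = al.wls_fit(y, X, rng.uniform(1, 4, 10))
        assert np.allclose(res.residuals, 0.0, atol=1e-10)
        assert res.r2_adj == pytest.approx(1.0)

    def test_unit_weights_equal_normal_equations_ols(self):
        rng = np.random.default_rng(1)
        y, X, _ = random_problem(rng)
        res = al.wls_fit(y, X, np.ones(len(y)))
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)  # independent oracle
        assert np.allclose(res.params.to_numpy(), beta_ne, atol=1e-10)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(2)
        y, X, w = random_problem(rng)
        a = al.wls_fit(y, X, w)
        b = al.wls_fit(y, X, 2.0 * w)
        assert np.allclose(a.params, b.params, atol=1e-12)
        # SEs also invariant: sigma2 absorbs the rescaling
        assert np.allclose(a.se, b.se, rtol=1e-10)

    def test_matches_statsmodels_wls(self):
        """Independent cross-check of estimates, SEs and log-likelihood."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        y, X, w = random_problem(rng, n=60, p=5)
        mine = al.wls_fit(y, X, w)
        ref = sm.WLS(y, X, weights=w).fit()
        assert np.allclose(mine.params, ref.params, atol=1e-10)
        assert np.allclose(mine.se, ref.bse, rtol=1e-8)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-6)
        # same likelihood, but our AIC counts sigma^2 as a parameter
        assert mine.aic == pytest.approx(ref.aic + 2.0, abs=1e-6)

    def test_rank_deficiency_names_collinear_column(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            al.wls_fit(np.arange(10.0), X, np.ones(10), ["c0", "c1", "c2"])

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            al.wls_fit(np.arange(4.0), np.ones((4, 1)), np.array([1, 0, 1, 1.0]))

    def test_oracle_equivalence_100_random_problems(self):
        """wls_fit equals the closed-form weighted normal equations to 1e-10."""
        rng = np.random.default_rng(20140903)
        for _ in range(100):
            y, X, w = random_problem(rng, n=int(rng.integers(10, 80)),
                                     p=int(rng.integers(2, 6)))
            res = al.wls_fit(y, X, w)
            beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
            assert np.max(np.abs(res.params.to_numpy() - beta)) < 1e-10


class TestFitModel:
    def test_named_coefficients_in_table_order(self, paper_scale_fit):
        _, _, f1, f3 = paper_scale_fit
        assert list(f1.params.index) == ["mu", "beta1", "delta", "gamma_prev_max"]
        assert list(f3.params.index) == (
            ["mu"] + [f"theta_{k}" for k in range(10)] + ["delta", "gamma_prev_max"]
        )

    def test_fit_table_excludes_intercept(self, paper_scale_fit):
        _, _, f1, _ = paper_scale_fit
        tab = fit_table(f1)
        assert list(tab.columns) == ["Coefficient", "Estimate", "Standard error",
                                     "p-value"]
        assert len(tab) == 3 and "mu" not in set(tab.Coefficient)

    def test_estimates_near_truth_on_one_study(self, paper_scale_fit):
        _, _, f1, _ = paper_scale_fit
        assert f1.params["beta1"] == pytest.approx(-15.0, abs=3 * f1.se["beta1"])
        assert f1.params["delta"] == pytest.approx(-20.0, abs=3 * f1.se["delta"])

    def test_model2_uses_prev_tsm(self, paper_scale_fit):
        temps, rec, _, _ = paper_scale_fit
        f2 = al.fit_model(rec, temps, al.DesignSpec(2, 123))
        assert "gamma_prev_tsm" in f2.params.index


class TestLagCurve:
    def test_constant_basis_curve_equals_model1_beta(self, paper_scale_fit):
        temps, rec, f1, _ = paper_scale_fit
        f3flat = al.fit_model(rec, temps, al.DesignSpec(3, 123, K=0, degree=0))
        curve = al.lag_curve(f3flat)
        assert np.allclose(curve.estimate, f1.params["beta1"], atol=1e-8)
        assert np.ptp(curve.estimate) < 1e-10

    def test_oracle_spline_evaluation(self, paper_scale_fit):
        _, _, _, f3 = paper_scale_fit
        curve = al.lag_curve(f3)
        theta = f3.theta.to_numpy()
        basis = f3.basis
        for l in (1, 30, 64, 123):
            assert curve.estimate[l - 1] == pytest.approx(
                float(basis.B[l - 1] @ theta), abs=1e-12
            )

    def test_zero_covariance_gives_zero_width_band(self, paper_scale_fit):
        _, _, _, f3 = paper_scale_fit
        from dataclasses import replace

        f0 = replace(f3, cov=f3.cov * 0.0)
        curve = al.lag_curve(f0)
        assert np.allclose(curve.lower, curve.estimate)
        assert np.allclose(curve.upper, curve.estimate)

    def test_bounds_bracket_estimate(self, paper_scale_fit):
        _, _, _, f3 = paper_scale_fit
        curve = al.lag_curve(f3)
        assert np.all(curve.lower <= curve.estimate)
        assert np.all(curve.estimate <= curve.upper)

    def test_dimension_mismatch_errors(self, paper_scale_fit):
        _, _, _, f3 = paper_scale_fit
        with pytest.raises(ValueError, match="basis"):
            al.lag_curve(f3, basis=al.bspline_lag_basis(123, K=4))

    def test_model1_fit_has_no_curve(self, paper_scale_fit):
        _, _, f1, _ = paper_scale_fit
        with pytest.raises(ValueError, match="lag basis|theta|spline"):
            al.lag_curve(f1)


class TestJointTest:
    def test_f_and_chi2_agree_on_statistic_scale(self, paper_scale_fit):
        _, _, _, f3 = paper_scale_fit
        ft = al.joint_dd5_test(f3, "f")
        ct = al.joint_dd5_test(f3, "chi2")
        assert ct.statistic == pytest.approx(ft.statistic * ft.df1)

    def test_strong_flat_signal_is_detected(self, paper_scale_fit):
        _, _, _, f3 = paper_scale_fit  # truth β₁ = −15 at every lag
        assert al.joint_dd5_test(f3).pvalue < 1e-6

    def test_zero_theta_gives_pvalue_one(self, paper_scale_fit):
        from dataclasses import replace

        _, _, _, f3 = paper_scale_fit
        f0 = replace(f3, params=f3.params * 0.0)
        t = al.joint_dd5_test(f0)
        assert t.statistic == pytest.approx(0.0) and t.pvalue == pytest.approx(1.0)


class TestProfileL:
    def test_grid_of_length_one(self, paper_scale_fit):
        temps, rec, _, _ = paper_scale_fit
        prof = al.profile_L(rec, temps, al.DesignSpec(1, 60), [60])
        assert prof.best_L == 60 and len(prof.aic) == 1

    def test_profile_aic_matches_direct_fit(self, paper_scale_fit):
        temps, rec, f1, _ = paper_scale_fit
        prof = al.profile_L(rec, temps, al.DesignSpec(1, 60), [100, 123, 150])
        direct = al.fit_model(rec, temps, al.DesignSpec(1, 123))
        i = list(prof.L_values).index(123)
        assert prof.aic[i] == pytest.approx(direct.aic)

    def test_unsorted_duplicate_grid_normalized_and_best_attains_min(
        self, paper_scale_fit
    ):
        temps, rec, _, _ = paper_scale_fit
        prof = al.profile_L(rec, temps, al.DesignSpec(1, 60), [150, 100, 123, 100])
        assert list(prof.L_values) == [100, 123, 150]
        i = list(prof.L_values).index(prof.best_L)
        assert prof.aic[i] == prof.aic.min()

    def test_infeasible_L_dropped(self, paper_scale_fit):
        temps, rec, _, _ = paper_scale_fit
        huge = 10_000  # far beyond temperature coverage
        prof = al.profile_L(rec, temps, al.DesignSpec(1, 60), [100, 123, huge])
        assert huge not in prof.L_values
        assert prof.best_L in (100, 123)


class TestRandomYearGls:
    def test_forced_zero_tau_reproduces_wls(self, paper_scale_fit):
        temps, rec, f1, _ = paper_scale_fit
        g = al.fit_random_year_gls(rec, temps, al.DesignSpec(1, 123), tau2=0.0)
        assert np.allclose(g.params, f1.params, atol=1e-10)
        assert np.allclose(g.cov, f1.cov, atol=1e-8)

    def test_single_plot_per_year_reduces_to_wls(self, paper_scale_config):
        cfg = paper_scale_config.with_(plots_min=1, plots_max=1)
        temps, rec = al.simulate_records(cfg, 9)
        spec = al.DesignSpec(1, 123)
        f = al.fit_model(rec, temps, spec)
        g = al.fit_random_year_gls(rec, temps, spec)
        assert g.extra["tau2"] == 0.0
        assert np.allclose(g.params, f.params, atol=1e-10)

    def test_estimated_on_independent_data_stays_close_to_wls(self, paper_scale_fit):
        temps, rec, f1, _ = paper_scale_fit  # generated with no year effect
        g = al.fit_random_year_gls(rec, temps, al.DesignSpec(1, 123))
        assert 0.0 <= g.extra["rho"] < 1.0
        assert np.allclose(g.params["beta1"], f1.params["beta1"],
                           atol=2.0 * f1.se["beta1"])

    def test_negative_tau2_clipped_with_warning(self, paper_scale_fit):
        temps, rec, _, _ = paper_scale_fit
        with pytest.warns(UserWarning, match="clipped"):
            g = al.fit_random_year_gls(rec, temps, al.DesignSpec(1, 123), tau2=-1.0)
        assert g.extra["tau2"] == 0.0


class TestCompareModels:
    def test_identical_fits_have_zero_delta(self, paper_scale_fit):
        _, _, f1, _ = paper_scale_fit
        tab = al.compare_models([f1, f1])
        assert np.allclose(tab.delta_aic, 0.0)

    def test_mismatched_record_sets_rejected(self, paper_scale_fit):
        temps, rec, f1, _ = paper_scale_fit
        small = al.fit_model(rec.iloc[:-6], temps, al.DesignSpec(1, 123))
        with pytest.raises(ValueError, match="not comparable"):
            al.compare_models([f1, small])

    def test_junk_column_pays_aic_penalty_on_average(self):
        """Adding a pure-noise regressor should not improve expected AIC."""
        rng = np.random.default_rng(5)
        deltas = []
        for _ in range(60):
            y, X, w = random_problem(rng, n=50, p=3)
            junk = np.column_stack([X, rng.normal(size=50)])
            deltas.append(al.wls_fit(y, junk, w).aic - al.wls_fit(y, X, w).aic)
        assert np.mean(deltas) > 0.0

    def test_lag_varying_truth_prefers_model3(self, paper_scale_config):
        cfg = paper_scale_config.with_(lag_curve=al.bimodal_lag_curve(123))
        wins = 0
        for seed in range(10):
            temps, rec = al.simulate_records(cfg, seed)
            f1 = al.fit_model(rec, temps, al.DesignSpec(1, 123))
            f3 = al.fit_model(rec, temps, al.DesignSpec(3, 123))
            wins += f3.aic < f1.aic
        assert wins >= 9
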