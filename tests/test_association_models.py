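"""Standardization, hierarchical OLS, simple slopes and correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from hrvstress.association_models import (
    FOCAL,
    INTERACTION,
    MODERATOR,
    FloorEffectRefusal,
    correlation_table,
    fit_hierarchical,
    fit_summary_dict,
    fit_summary_table,
    simple_slopes,
    standardize,
)
from hrvstress.synthetic import simulate_window_sample
from hrvstress.trend_windows import TREND_COLUMNS

ANALYSIS_VARS = TREND_COLUMNS + ["stress_increase"]


def window_sample(n=200, gamma=None, seed=0, noise=0.8):
    return simulate_window_sample(n, gamma, outcome_noise_sd=noise, rng=seed)


class TestStandardize:
    def test_columns_mean_zero_sd_one(self):
        s = standardize(window_sample(60), ANALYSIS_VARS)
        z = s.data[ANALYSIS_VARS]
        assert np.allclose(z.mean(), 0.0, atol=1e-9)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-9)

    def test_three_values_hand_case(self):
        df = pd.DataFrame({"hrv_uptrend": [1.0, 2.0, 3.0]})
        s = standardize(df, ["hrv_uptrend"])
        assert np.allclose(s.data["hrv_uptrend"], [-1.0, 0.0, 1.0])
        assert s.means["hrv_uptrend"] == pytest.approx(2.0)
        assert s.sds["hrv_uptrend"] == pytest.approx(1.0)

    def test_constant_column_errors(self):
        df = pd.DataFrame({"hrv_uptrend": [1.0, 1.0, 1.0], "hrvsd_uptrend": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="hrv_uptrend"):
            standardize(df, ["hrv_uptrend", "hrvsd_uptrend"])

    def test_listwise_deletion_counted(self):
        df = window_sample(30)
        df.loc[3, "hrvsd_uptrend"] = np.nan
        df.loc[8, "stress_increase"] = np.nan
        s = standardize(df, ANALYSIS_VARS)
        assert s.n == 28 and s.n_dropped == 2


class TestFitHierarchical:
    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            df = window_sample(rng.integers(40, 120), seed=int(rng.integers(2**31)))
            s = standardize(df, ANALYSIS_VARS)
            fit = fit_hierarchical(s, "stress_increase")
            y = s.data["stress_increase"].to_numpy()
            X = s.data[fit.step3().terms[:-1]].to_numpy()
            X = np.column_stack([X, s.data[MODERATOR] * s.data[FOCAL]])
            X = np.column_stack([np.ones(len(X)), X])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            got = fit.step3().params.to_numpy()
            assert np.allclose(got, beta, atol=1e-8)

    def test_r2_non_decreasing_and_nested_terms(self):
        s = standardize(window_sample(80), ANALYSIS_VARS)
        fit = fit_hierarchical(s, "stress_increase")
        r2 = [st.r2 for st in fit.steps]
        assert r2[0] <= r2[1] <= r2[2]
        assert fit.steps[2].terms == fit.steps[1].terms + [INTERACTION]
        assert fit.delta_r2[2] == pytest.approx(r2[1] - r2[0])
        assert fit.delta_r2[3] == pytest.approx(r2[2] - r2[1])

    def test_null_outcome_low_r2(self):
        gamma = {k: 0.0 for k in ("hrv", "hrvsd", "int", "tst", "mvpa", "alcohol")}
        s = standardize(window_sample(500, gamma, seed=11, noise=1.0), ANALYSIS_VARS)
        fit = fit_hierarchical(s, "stress_increase")
        assert all(st.r2 < 0.05 for st in fit.steps)

    def test_effect_recovery_step2(self):
        gamma = {"hrvsd": 0.6}
        s = standardize(window_sample(500, gamma, seed=5), ANALYSIS_VARS)
        fit = fit_hierarchical(s, "stress_increase")
        assert fit.steps[1].params["hrvsd_uptrend"] == pytest.approx(0.6, abs=0.1)

    def test_delta_f_is_difference_of_model_f(self):
        s = standardize(window_sample(60), ANALYSIS_VARS)
        fit = fit_hierarchical(s, "stress_increase")
        assert fit.delta_f[2] == pytest.approx(fit.steps[1].f_stat - fit.steps[0].f_stat)
        assert fit.delta_f[3] == pytest.approx(fit.steps[2].f_stat - fit.steps[1].f_stat)

    def test_comparison_p_matches_partial_f(self):
        s = standardize(window_sample(60), ANALYSIS_VARS)
        fit = fit_hierarchical(s, "stress_increase")
        s1, s2 = fit.steps[0], fit.steps[1]
        n = s.n
        num = (s2.r2 - s1.r2) / 2
        den = (1 - s2.r2) / (n - 5 - 1)
        p = scipy.stats.f.sf(num / den, 2, n - 5 - 1)
        assert fit.comparison_p[2] == pytest.approx(p, rel=1e-6)

    def test_floor_flag_refusal_and_force(self):
        s = standardize(window_sample(40), ANALYSIS_VARS)
        with pytest.raises(FloorEffectRefusal, match="no models could be formed"):
            fit_hierarchical(s, "stress_increase", floor_flagged=True)
        fit = fit_hierarchical(s, "stress_increase", floor_flagged=True, force=True)
        assert len(fit.steps) == 3

    def test_rank_deficient_design_errors(self):
        df = window_sample(40)
        df["tst_uptrend"] = df["mvpa_uptrend"]
        s = standardize(df, ANALYSIS_VARS)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_hierarchical(s, "stress_increase")

    def test_cluster_robust_changes_se_not_beta(self):
        df = window_sample(60)
        df["participant_id"] = np.repeat([f"P{i}" for i in range(6)], 10)
        s = standardize(df, ANALYSIS_VARS)
        plain = fit_hierarchical(s, "stress_increase")
        robust = fit_hierarchical(s, "stress_increase", cluster_robust=True)
        assert np.allclose(plain.step3().params, robust.step3().params)
        assert not np.allclose(plain.step3().bse, robust.step3().bse)


class TestSimpleSlopes:
    def _fit(self, n=300, seed=3):
        s = standardize(window_sample(n, seed=seed), ANALYSIS_VARS)
        return s, fit_hierarchical(s, "stress_increase")

    def test_slope_at_zero_equals_focal_beta(self):
        _, fit = self._fit()
        prof = simple_slopes(fit, np.array([0.0]))
        assert prof.slope[0] == pytest.approx(float(fit.step3().params[FOCAL]), abs=1e-12)
        assert prof.se[0] == pytest.approx(float(fit.step3().bse[FOCAL]), abs=1e-12)

    def test_arithmetic_identity(self):
        # slope at h is focal beta plus h times the interaction beta
        _, fit = self._fit()
        b_sd = float(fit.step3().params[FOCAL])
        b_int = float(fit.step3().params[INTERACTION])
        prof = simple_slopes(fit, np.array([1.0, -2.5]))
        assert prof.slope[0] == pytest.approx(b_sd + b_int)
        assert prof.slope[1] == pytest.approx(b_sd - 2.5 * b_int)

    def test_matches_recentred_refit_oracle(self):
        # refitting with the moderator re-centred at h must reproduce the
        # conditional slope and its SE as the focal main effect
        s, fit = self._fit()
        h = 0.8
        df = s.data.copy()
        df["mod_c"] = df[MODERATOR] - h
        X = df[["tst_uptrend", "mvpa_uptrend", "alcohol_uptrend", "mod_c", FOCAL]].copy()
        X[INTERACTION] = X["mod_c"] * X[FOCAL]
        res = sm.OLS(df["stress_increase"], sm.add_constant(X)).fit()
        prof = simple_slopes(fit, np.array([h]))
        assert prof.slope[0] == pytest.approx(float(res.params[FOCAL]), abs=1e-10)
        assert prof.se[0] == pytest.approx(float(res.bse[FOCAL]), abs=1e-10)

    def test_ci_uses_t_distribution(self):
        _, fit = self._fit()
        prof = simple_slopes(fit, np.array([0.5]))
        tcrit = scipy.stats.t.ppf(0.975, prof.df_resid)
        assert prof.ci_high[0] - prof.slope[0] == pytest.approx(tcrit * prof.se[0])


class TestCorrelationTable:
    def test_perfect_negative_correlation(self):
        df = pd.DataFrame({"hrv_uptrend": np.arange(10.0)})
        df["hrvsd_uptrend"] = -df["hrv_uptrend"]
        out = correlation_table(df, ["hrv_uptrend", "hrvsd_uptrend"])
        assert out["r"].iloc[0] == pytest.approx(-1.0)
        assert out["stars"].iloc[0] == "***"

    def test_independent_columns_small_r(self):
        df = window_sample(1000, {k: 0.0 for k in ("hrv", "hrvsd", "int", "tst", "mvpa", "alcohol")}, seed=9)
        out = correlation_table(df, ["hrv_uptrend", "hrvsd_uptrend", "tst_uptrend"])
        assert (out["r"].abs() < 0.1).all()

    def test_pairwise_complete_counts(self):
        df = window_sample(50)
        df.loc[0:4, "hrv_uptrend"] = np.nan
        out = correlation_table(df, ["hrv_uptrend", "hrvsd_uptrend"])
        assert out["n"].iloc[0] == 45


def test_summary_tables_shape():
    s = standardize(window_sample(60), ANALYSIS_VARS)
    fit = fit_hierarchical(s, "stress_increase")
    table = fit_summary_table(fit)
    # steps carry 3+1, 5+1 and 6+1 terms including the intercept
    assert list(table.groupby("step").size()) == [4, 6, 7]
    d = fit_summary_dict(fit)
    assert set(d["steps"]) == {"1", "2", "3"}
    assert d["steps"]["2"]["delta_r2"] == pytest.approx(fit.delta_r2[2])
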