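"""Synthetic cohort generator: determinism, structure, induced effects."""

import numpy as np
import pandas as pd
import pytest

from hrvstress.daily_features import build_daily_table, rolling_sd
from hrvstress.hrv_nightly import process_night
from hrvstress.questionnaire import SCALE_MAXIMA, floor_effect_check, score_table
from hrvstress.synthetic import (
    SimConfig,
    simulate_cohort,
    simulate_ibi_night,
    simulate_nightly,
    simulate_outcomes,
    simulate_window_sample,
)
from hrvstress.trend_windows import trend_beta


class TestSimConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown SimConfig keys"):
            SimConfig.from_dict({"n_participants": 3, "weeks": [15, 15, 15]})

    def test_rate_bounds_checked(self):
        with pytest.raises(ValueError, match="hrv_missing_rate"):
            SimConfig(hrv_missing_rate=1.5)

    def test_weeks_length_must_match(self):
        with pytest.raises(ValueError, match="weeks_per_participant"):
            SimConfig(n_participants=2, weeks_per_participant=(15,))

    def test_default_cohort_shape(self):
        cfg = SimConfig()
        assert cfg.n_participants == 9
        assert min(cfg.weeks_per_participant) == 15
        assert max(cfg.weeks_per_participant) == 55
        assert sum(w // 5 for w in cfg.weeks_per_participant) == 47


class TestSimulateNightly:
    def test_degenerate_noise_near_constant(self):
        rng = np.random.default_rng(0)
        s = simulate_nightly(rng, 35, 4.0, np.zeros(1), np.zeros(1), 35,
                             sigma0=0.001, sigma_min=0.0005, missing_rate=0.0)
        assert np.nanstd(s) < 0.005
        dates = pd.date_range("2020-07-01", periods=35)
        sd = rolling_sd(pd.Series(s, index=dates))
        assert np.nanmax(sd) < 0.005

    def test_dispersion_drift_induces_hrvsd_uptrend(self):
        # rising sigma(t) should make the realized rolling SD trend upward
        hits = 0
        reps = 100
        dates = pd.date_range("2020-07-01", periods=35)
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            s = simulate_nightly(rng, 35, 4.0, np.zeros(1), np.array([0.006]), 35,
                                 sigma0=0.1, sigma_min=0.02, missing_rate=0.0)
            sd = rolling_sd(pd.Series(s, index=dates))
            slope, _ = trend_beta(dates.date, sd.to_numpy(), min_trend_obs=10)
            hits += slope > 0
        assert hits / reps >= 0.95

    def test_same_seed_identical(self):
        a = simulate_nightly(np.random.default_rng(7), 100, 4.0, np.array([0.01]),
                             np.array([0.001]), 100, 0.25, 0.02, 0.06)
        b = simulate_nightly(np.random.default_rng(7), 100, 4.0, np.array([0.01]),
                             np.array([0.001]), 100, 0.25, 0.02, 0.06)
        assert np.array_equal(a, b, equal_nan=True)


class TestSimulateOutcomes:
    def test_null_gamma_no_association(self):
        rng = np.random.default_rng(2)
        n = 1000
        z = {k: rng.normal(0, 1, n) for k in ("hrv", "hrvsd", "tst", "mvpa", "alcohol")}
        gamma = {k: 0.0 for k in ("hrv", "hrvsd", "int", "tst", "mvpa", "alcohol")}
        delta = simulate_outcomes(rng, z, gamma, noise_sd=1.0)
        for k in ("hrv", "hrvsd", "tst"):
            assert abs(np.corrcoef(z[k], delta)[0, 1]) < 0.07

    def test_configured_effect_recovered_end_to_end(self):
        from hrvstress.association_models import fit_hierarchical, standardize
        from hrvstress.trend_windows import TREND_COLUMNS

        df = simulate_window_sample(500, {"hrvsd": 0.5}, rng=3)
        s = standardize(df, TREND_COLUMNS + ["stress_increase"])
        fit = fit_hierarchical(s, "stress_increase")
        assert fit.steps[1].params["hrvsd_uptrend"] == pytest.approx(0.5, abs=0.1)

    def test_floor_parameter_one_gives_all_zero(self):
        cfg = SimConfig(seed=5, floor_zero_prob=1.0)
        cohort = simulate_cohort(cfg)
        scored = score_table(cohort.responses)
        dep = [s.depression for pid in scored for s in scored[pid]]
        assert all(v == 0 for v in dep)
        assert floor_effect_check(dep, "depression").flagged


class TestSimulateCohort:
    def test_window_count_identity(self, default_cohort):
        per_participant = default_cohort.truth.groupby("participant_id").size()
        for pid, n in per_participant.items():
            assert n == len(default_cohort.questionnaire_dates[pid]) - 1
        assert per_participant.sum() == 47

    def test_missing_fraction_near_target(self):
        cfg = SimConfig(
            n_participants=2, weeks_per_participant=(55, 55), seed=9
        )
        cohort = simulate_cohort(cfg)
        n_days = len(cohort.activity)
        realized_missing = 1 - len(cohort.nightly_hrv) / n_days
        assert realized_missing == pytest.approx(cfg.hrv_missing_rate, abs=0.015)

    def test_same_seed_byte_identical_csv(self, tmp_path):
        a = simulate_cohort(SimConfig(seed=3))
        b = simulate_cohort(SimConfig(seed=3))
        for name in ("nightly_hrv", "ema", "activity", "responses", "truth"):
            fa, fb = tmp_path / f"a_{name}.csv", tmp_path / f"b_{name}.csv"
            getattr(a, name).to_csv(fa, index=False)
            getattr(b, name).to_csv(fb, index=False)
            assert fa.read_bytes() == fb.read_bytes()

    def test_scores_respect_scale_bounds(self, default_cohort):
        scored = score_table(default_cohort.responses)
        for pid, lst in scored.items():
            for s in lst:
                for scale, mx in SCALE_MAXIMA.items():
                    assert 0 <= getattr(s, scale) <= mx

    def test_daily_dates_continuous(self, default_cohort):
        daily = build_daily_table(
            default_cohort.nightly_hrv, default_cohort.ema, default_cohort.activity
        )
        for pid, grp in daily.groupby("participant_id"):
            d = pd.to_datetime(pd.Series(list(grp["date"])))
            assert (d.diff().dropna() == pd.Timedelta(days=1)).all()

    def test_item_responses_reproduce_target_scores(self, default_cohort):
        # the generated item categories must sum back to the generated scores
        scored = score_table(default_cohort.responses)
        assert all(
            s.stress is not None and s.somatisation is not None
            for lst in scored.values() for s in lst
        )


class TestSimulateIBINight:
    def test_rmssd_near_target(self):
        rng = np.random.default_rng(4)
        night = simulate_ibi_night(rng, target_rmssd_ms=40.0, duration_minutes=60)
        out = process_night(night)
        assert out.rmssd_ms == pytest.approx(40.0, rel=0.15)

    def test_artifacts_are_screened_out(self):
        rng = np.random.default_rng(6)
        clean = simulate_ibi_night(np.random.default_rng(6), 30.0, 60, artifact_rate=0.0)
        noisy = simulate_ibi_night(np.random.default_rng(6), 30.0, 60, artifact_rate=0.03)
        r_clean = process_night(clean).rmssd_ms
        r_noisy = process_night(noisy).rmssd_ms
        # screening keeps the corrupted night in the clean night's ballpark
        assert r_noisy == pytest.approx(r_clean, rel=0.35)
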