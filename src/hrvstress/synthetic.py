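"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a small occupational cohort wearing a sleep-tracking
ring for 15–55 weeks with a questionnaire every five weeks: per participant a
nightly lnRMSSD series whose *level* and *dispersion* drift linearly within
each between-questionnaire window, daily total sleep time and activity with
their own mild trends, a daily alcohol EMA with realistic missingness, and
five-weekly questionnaire scores whose changes are driven by the latent
window slopes through a configurable standardized effect vector γ (including
the HRV × HRVsd product term).  Depression and anxiety are generated from a
zero-inflated count so the floor effects that block modelling of those scales
can be reproduced on demand.

The latent truth (per-window slopes, their standardized values, the γ used)
is returned alongside the data so parameter-recovery tests can compare what
the pipeline estimates with what generated the data.

Two levels of generation are exposed:

* :func:`simulate_cohort` — the full daily-level cohort, consumed by the
  pipeline end-to-end (nightly table → daily table → windows → models);
* :func:`simulate_window_sample` — window-level draws on the standardized
  scale, the fast path for recovery and power experiments where thousands of
  analysis units are needed and the daily measurement layer is not under
  test.

Everything is driven by one integer seed; the same config reproduces the
cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date as Date
from datetime import timedelta
import numpy as np
import pandas as pd

from .questionnaire import DEFAULT_ITEM_MAP, SCALE_MAXIMA, SCALES
from .hrv_nightly import NightIBISeries

#: Per-participant study lengths, weeks.  Nine participants spanning 15–55
#: weeks whose five-week windows total exactly 47 — the cohort shape the
#: analysis is sized for.
DEFAULT_WEEKS = (15, 15, 15, 20, 25, 25, 25, 40, 55)

GAMMA_KEYS = ("hrv", "hrvsd", "int", "tst", "mvpa", "alcohol")


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; the defaults are the study conditions.

    Rates come from the reported completeness of the source cohort (94.3%
    nightly HRV, 89.0% EMA); effect sizes γ are on the standardized scale of
    the association models; slope SDs are in variable units per day.
    """

    n_participants: int = 9
    weeks_per_participant: tuple[int, ...] = DEFAULT_WEEKS
    questionnaire_interval_days: int = 35
    start_date: str = "2020-07-01"

    # nightly lnRMSSD process
    baseline_ln_rmssd_mean: float = 4.1   # ln ms; exp(4.1) ≈ 60 ms RMSSD
    baseline_ln_rmssd_sd: float = 0.3     # between-participant spread
    level_slope_sd: float = 0.01          # per-window level drift, ln ms / day
    dispersion_slope_sd: float = 0.003    # per-window drift of nightly SD / day
    nightly_noise_sd: float = 0.25        # σ0: nightly lnRMSSD SD at window start
    sigma_min: float = 0.02               # dispersion floor after drift

    # missingness
    hrv_missing_rate: float = 0.057
    ema_missing_rate: float = 0.11

    # control variables (daily)
    tst_mean_min: float = 430.0
    tst_between_sd: float = 30.0
    tst_daily_sd: float = 40.0
    tst_slope_sd: float = 0.5             # min / day per window
    mvpa_mean_min: float = 45.0
    mvpa_daily_sd: float = 15.0
    mvpa_slope_sd: float = 0.3
    alcohol_lambda: float = 0.6           # drinks / day
    alcohol_slope_sd: float = 0.01        # drift of the Poisson mean / day

    # questionnaire outcome process
    gamma: dict[str, float] = field(
        default_factory=lambda: {
            "hrv": -0.1, "hrvsd": 0.5, "int": -0.4,
            "tst": 0.05, "mvpa": -0.2, "alcohol": 0.0,
        }
    )
    outcome_noise_sd: float = 0.8         # residual SD of standardized change
    outcome_scale_points: float = 4.0     # raw scale points per 1 SD of change
    stress_start_mean: float = 8.0
    somatisation_start_mean: float = 7.0
    start_sd: float = 3.0
    floor_zero_prob: float = 0.9          # depression/anxiety zero inflation

    # optional IBI-level mode (exercises the per-night pipeline; slow)
    ibi_mode: bool = False
    ibi_mean_ms: float = 1000.0
    ibi_artifact_rate: float = 0.02
    night_minutes: int = 360

    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.weeks_per_participant) != self.n_participants:
            raise ValueError("weeks_per_participant length must equal n_participants")
        for name in ("hrv_missing_rate", "ema_missing_rate", "floor_zero_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.questionnaire_interval_days < 7:
            raise ValueError("questionnaire_interval_days must be >= 7")
        extra = set(self.gamma) - set(GAMMA_KEYS)
        if extra:
            raise ValueError(f"unknown gamma keys: {sorted(extra)}")
        object.__setattr__(
            self, "gamma", {k: float(self.gamma.get(k, 0.0)) for k in GAMMA_KEYS}
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        if "weeks_per_participant" in d:
            d = {**d, "weeks_per_participant": tuple(d["weeks_per_participant"])}
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weeks_per_participant"] = list(d["weeks_per_participant"])
        return d


@dataclass
class SyntheticCohort:
    """A generated cohort plus the latent truth behind it."""

    nightly_hrv: pd.DataFrame     # nightly_hrv.csv schema (observed nights only)
    ema: pd.DataFrame             # participant_id, timestamp, drinks
    activity: pd.DataFrame        # participant_id, date, tst_min, mvpa_min
    responses: pd.DataFrame       # participant_id, date, item_1..item_50 categories
    questionnaire_dates: dict[str, list[Date]]
    truth: pd.DataFrame           # per-window latent slopes, z-values, outcomes
    config: SimConfig


def _participant_ids(n: int) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(n)]


def simulate_nightly(
    rng: np.random.Generator,
    n_days: int,
    baseline: float,
    level_slopes: np.ndarray,
    dispersion_slopes: np.ndarray,
    window_days: int,
    sigma0: float,
    sigma_min: float,
    missing_rate: float,
) -> np.ndarray:
    """One participant's nightly lnRMSSD series with NaN for missing nights.

    Within window k, ln_rmssd(t) = level(t) + ε(t) with ε ~ N(0, σ(t));
    level and σ both drift linearly at the window's latent slopes and carry
    over continuously across window boundaries.  σ is truncated below at
    ``sigma_min``.  Nights are removed independently at ``missing_rate``.
    """
    t = np.arange(n_days, dtype=float)
    k = np.minimum(t // window_days, len(level_slopes) - 1).astype(int)
    within = t - k * window_days

    lvl_cum = np.concatenate([[0.0], np.cumsum(level_slopes[:-1] * window_days)])
    sd_cum = np.concatenate([[0.0], np.cumsum(dispersion_slopes[:-1] * window_days)])
    level = baseline + lvl_cum[k] + level_slopes[k] * within
    sigma = np.maximum(sigma0 + sd_cum[k] + dispersion_slopes[k] * within, sigma_min)

    series = level + rng.normal(0.0, 1.0, n_days) * sigma
    missing = rng.random(n_days) < missing_rate
    series[missing] = np.nan
    return series


def simulate_outcomes(
    rng: np.random.Generator,
    z: dict[str, np.ndarray],
    gamma: dict[str, float],
    noise_sd: float,
) -> np.ndarray:
    """Standardized outcome changes Δ* from standardized latent slopes.

    Δ* = γ_hrv·z_hrv + γ_hrvsd·z_hrvsd + γ_int·z_hrv·z_hrvsd
       + γ_tst·z_tst + γ_mvpa·z_mvpa + γ_alc·z_alc + N(0, noise_sd).
    """
    n = len(z["hrv"])
    delta = (
        gamma["hrv"] * z["hrv"]
        + gamma["hrvsd"] * z["hrvsd"]
        + gamma["int"] * z["hrv"] * z["hrvsd"]
        + gamma["tst"] * z["tst"]
        + gamma["mvpa"] * z["mvpa"]
        + gamma["alcohol"] * z["alcohol"]
    )
    return delta + rng.normal(0.0, noise_sd, n)


def _score_path(
    rng: np.random.Generator,
    deltas: np.ndarray,
    start_mean: float,
    start_sd: float,
    scale_points: float,
    maximum: int,
) -> np.ndarray:
    """Integer score path by cumulative rounding of the latent change path."""
    latent = float(np.clip(rng.normal(start_mean, start_sd), 0.0, maximum))
    scores = [int(round(latent))]
    for d in deltas:
        latent = float(np.clip(latent + scale_points * d, 0.0, maximum))
        scores.append(int(round(latent)))
    return np.array(scores, dtype=int)


def _floor_scores(rng: np.random.Generator, n: int, zero_prob: float, maximum: int) -> np.ndarray:
    """Zero-inflated counts reproducing a floor-effected scale."""
    nonzero = rng.random(n) >= zero_prob
    counts = 1 + rng.poisson(1.0, n)
    return np.where(nonzero, np.minimum(counts, maximum), 0).astype(int)


def _items_for_scores(rng: np.random.Generator, scores: dict[str, int]) -> dict[str, str]:
    """Build a 50-item response set whose scale sums equal ``scores``.

    For each scale, the target sum S is decomposed into S // 2 items at
    category 2 and S % 2 at category 1, placed on randomly chosen items of
    the scale; category-2 responses draw uniformly among the three
    equivalently scored labels.  The unassigned 50th item is answered 'no'.
    """
    two_labels = ("regularly", "often", "very_often")
    by_scale: dict[str, list[int]] = {s: [] for s in SCALES}
    for idx, scale in DEFAULT_ITEM_MAP.items():
        by_scale[scale].append(idx)
    items = {f"item_{i}": "no" for i in range(1, 51)}
    for scale, indices in by_scale.items():
        s = int(scores[scale])
        chosen = rng.permutation(indices)
        n2, n1 = s // 2, s % 2
        for idx in chosen[:n2]:
            items[f"item_{idx}"] = two_labels[rng.integers(len(two_labels))]
        for idx in chosen[n2 : n2 + n1]:
            items[f"item_{idx}"] = "sometimes"
    return items


def simulate_ibi_night(
    rng: np.random.Generator,
    target_rmssd_ms: float,
    duration_minutes: int = 360,
    mean_ibi_ms: float = 1000.0,
    artifact_rate: float = 0.0,
    ar_coef: float = 0.9,
) -> NightIBISeries:
    """Synthesize one night of IBIs with a chosen expected RMSSD.

    IBIs follow a stationary AR(1) around ``mean_ibi_ms`` whose innovation SD
    is calibrated so the successive-difference variance equals
    ``target_rmssd_ms``²; ectopic beats (interval nearly doubled) are injected
    independently at ``artifact_rate`` to exercise artifact screening.
    """
    n = int(duration_minutes * 60_000 / mean_ibi_ms) + 1
    innov_sd = target_rmssd_ms * np.sqrt((1 + ar_coef) / 2.0)
    stat_sd = innov_sd / np.sqrt(1 - ar_coef**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, stat_sd)
    e = rng.normal(0.0, innov_sd, n - 1)
    for i in range(1, n):
        x[i] = ar_coef * x[i - 1] + e[i - 1]
    ibis = np.maximum(mean_ibi_ms + x, 300.0)
    if artifact_rate > 0:
        ect = rng.random(n) < artifact_rate
        ibis = np.where(ect, ibis * 1.9, ibis)
    timestamps = np.cumsum(ibis) / 1000.0
    keep = timestamps < duration_minutes * 60.0
    return NightIBISeries("synthetic", Date(2020, 7, 1), timestamps[keep], ibis[keep])


def simulate_cohort(config: SimConfig | None = None) -> SyntheticCohort:
    """Generate the full daily-level cohort the pipeline consumes."""
    config = config or SimConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    interval = config.questionnaire_interval_days
    start0 = pd.Timestamp(config.start_date).date()

    hrv_rows, ema_rows, act_rows, resp_rows, truth_rows = [], [], [], [], []
    q_dates_all: dict[str, list[Date]] = {}

    for pid, weeks, ss in zip(
        _participant_ids(config.n_participants), config.weeks_per_participant, seeds
    ):
        rng = np.random.default_rng(ss)
        n_windows = weeks // 5
        n_days = n_windows * interval
        dates = [start0 + timedelta(days=i) for i in range(n_days)]
        q_dates = [start0 + timedelta(days=interval * k) for k in range(n_windows + 1)]
        q_dates_all[pid] = q_dates

        # latent per-window slopes
        a = rng.normal(0.0, config.level_slope_sd, n_windows)
        b = rng.normal(0.0, config.dispersion_slope_sd, n_windows)
        s_tst = rng.normal(0.0, config.tst_slope_sd, n_windows)
        s_mvpa = rng.normal(0.0, config.mvpa_slope_sd, n_windows)
        s_alc = rng.normal(0.0, config.alcohol_slope_sd, n_windows)

        baseline = rng.normal(config.baseline_ln_rmssd_mean, config.baseline_ln_rmssd_sd)
        ln_rmssd = simulate_nightly(
            rng, n_days, baseline, a, b, interval,
            config.nightly_noise_sd, config.sigma_min, config.hrv_missing_rate,
        )
        for d, v in zip(dates, ln_rmssd):
            if np.isfinite(v):
                hrv_rows.append((pid, d.isoformat(), float(np.exp(v)), float(v), 1, 1))

        # daily controls: piecewise-linear mean + daily noise
        t = np.arange(n_days, dtype=float)
        k = (t // interval).astype(int)
        within = t - k * interval
        tst_base = rng.normal(config.tst_mean_min, config.tst_between_sd)
        tst_cum = np.concatenate([[0.0], np.cumsum(s_tst[:-1] * interval)])
        tst = tst_base + tst_cum[k] + s_tst[k] * within + rng.normal(0, config.tst_daily_sd, n_days)
        tst = np.maximum(tst, 0.0)
        mvpa_cum = np.concatenate([[0.0], np.cumsum(s_mvpa[:-1] * interval)])
        mvpa = (
            config.mvpa_mean_min + mvpa_cum[k] + s_mvpa[k] * within
            + rng.normal(0, config.mvpa_daily_sd, n_days)
        )
        mvpa = np.maximum(mvpa, 0.0)
        for d, tv, mv in zip(dates, tst, mvpa):
            act_rows.append((pid, d.isoformat(), round(float(tv), 1), round(float(mv), 1)))

        alc_cum = np.concatenate([[0.0], np.cumsum(s_alc[:-1] * interval)])
        lam = np.maximum(config.alcohol_lambda + alc_cum[k] + s_alc[k] * within, 0.02)
        drinks = rng.poisson(lam)
        answered = rng.random(n_days) >= config.ema_missing_rate
        for d, cnt, ok in zip(dates, drinks, answered):
            if ok:
                # answered the same evening at 21:30, inside the 19:00–15:00 window
                ema_rows.append((pid, f"{d.isoformat()}T21:30:00", int(cnt)))

        # standardized latent slopes drive the questionnaire changes
        z = {
            "hrv": a / config.level_slope_sd,
            "hrvsd": b / config.dispersion_slope_sd,
            "tst": s_tst / config.tst_slope_sd,
            "mvpa": s_mvpa / config.mvpa_slope_sd,
            "alcohol": s_alc / config.alcohol_slope_sd,
        }
        delta_stress = simulate_outcomes(rng, z, config.gamma, config.outcome_noise_sd)
        delta_som = simulate_outcomes(rng, z, config.gamma, config.outcome_noise_sd)
        stress = _score_path(
            rng, delta_stress, config.stress_start_mean, config.start_sd,
            config.outcome_scale_points, SCALE_MAXIMA["stress"],
        )
        som = _score_path(
            rng, delta_som, config.somatisation_start_mean, config.start_sd,
            config.outcome_scale_points, SCALE_MAXIMA["somatisation"],
        )
        depression = _floor_scores(
            rng, n_windows + 1, config.floor_zero_prob, SCALE_MAXIMA["depression"]
        )
        anxiety = _floor_scores(
            rng, n_windows + 1, config.floor_zero_prob, SCALE_MAXIMA["anxiety"]
        )

        for j, qd in enumerate(q_dates):
            scores = {
                "stress": int(stress[j]),
                "anxiety": int(anxiety[j]),
                "depression": int(depression[j]),
                "somatisation": int(som[j]),
            }
            resp_rows.append(
                {"participant_id": pid, "date": qd.isoformat(),
                 **_items_for_scores(rng, scores)}
            )
        for j in range(n_windows):
            truth_rows.append(
                {
                    "participant_id": pid,
                    "window": j,
                    "start_date": q_dates[j].isoformat(),
                    "end_date": q_dates[j + 1].isoformat(),
                    "level_slope": a[j],
                    "dispersion_slope": b[j],
                    "tst_slope": s_tst[j],
                    "mvpa_slope": s_mvpa[j],
                    "alcohol_slope": s_alc[j],
                    "z_hrv": z["hrv"][j],
                    "z_hrvsd": z["hrvsd"][j],
                    "delta_stress": delta_stress[j],
                    "delta_somatisation": delta_som[j],
                }
            )

    nightly = pd.DataFrame(
        hrv_rows,
        columns=["participant_id", "night_date", "rmssd_ms", "ln_rmssd",
                 "n_valid_segments", "n_total_segments"],
    )
    ema = pd.DataFrame(ema_rows, columns=["participant_id", "timestamp", "drinks"])
    activity = pd.DataFrame(act_rows, columns=["participant_id", "date", "tst_min", "mvpa_min"])
    responses = pd.DataFrame(resp_rows)
    truth = pd.DataFrame(truth_rows)
    for k_, v in config.gamma.items():
        truth[f"gamma_{k_}"] = v
    return SyntheticCohort(nightly, ema, activity, responses, q_dates_all, truth, config)


def simulate_window_sample(
    n_windows: int,
    gamma: dict[str, float] | None = None,
    outcome_noise_sd: float = 0.8,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Window-level draws on the standardized scale (fast experiment path).

    Each row is one observation window: the five trend variables drawn iid
    standard normal (their grand-mean-standardized distribution) and the
    outcome change built by :func:`simulate_outcomes`.  Used for recovery and
    power experiments where the daily measurement layer is not under test.
    """
    if gamma is None:
        gamma = SimConfig().gamma
    else:
        gamma = {k: float(gamma.get(k, 0.0)) for k in GAMMA_KEYS}
    rng = np.random.default_rng(rng)
    z = {k: rng.normal(0.0, 1.0, n_windows) for k in ("hrv", "hrvsd", "tst", "mvpa", "alcohol")}
    outcome = simulate_outcomes(rng, z, gamma, outcome_noise_sd)
    return pd.DataFrame(
        {
            "participant_id": [f"W{i}" for i in range(n_windows)],
            "hrv_uptrend": z["hrv"],
            "hrvsd_uptrend": z["hrvsd"],
            "tst_uptrend": z["tst"],
            "mvpa_uptrend": z["mvpa"],
            "alcohol_uptrend": z["alcohol"],
            "stress_increase": outcome,
        }
    )
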