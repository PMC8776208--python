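# Methods

This note documents the statistical procedures, the synthetic data-generating
process, the defaults and the judgement calls behind `hrvstress`.

## 1. Nightly RMSSD from inter-beat intervals

**Artifact screening.** Each IBI is labelled abnormal when its absolute
deviation from the median of its `neighborhood` nearest surrounding IBIs
(itself excluded) exceeds `rel_threshold` × that median. Defaults:
`neighborhood = 5`, `rel_threshold = 0.30`. Consumer devices use proprietary
constants; these sit in the conventional range for median-filter ectopic-beat
screening and are config-exposed. Near the night's edges all available
neighbours are used; neighbours tied in index distance resolve toward the
earlier beat, making the rule deterministic.

**Segmentation and averaging.** The night is tiled into contiguous 5-minute
segments by timestamp (`floor(t / 300 s)`), trailing partial segment
included. A segment contributes when its normal-IBI fraction is ≥
`min_valid_fraction = 0.5` and it retains ≥ `min_normal_ibis = 30` normal
beats (both config-exposed — the device literature does not state its
thresholds). Per contributing segment, RMSSD = √(mean of squared successive
differences of the normal IBIs); the nightly value is the **unweighted** mean
of segment RMSSDs (weighting by valid-beat count is a plausible alternative
the source processing does not document; unweighted is the simpler default)
and lnRMSSD its natural log.

**Degenerate nights.** Zero contributing segments, or an RMSSD of exactly 0
(a constant-interval night — physiologically implausible, a sensor-failure
signature), produce a *missing* night rather than an exception or an
epsilon-padded log; downstream code handles missing days uniformly.

## 2. Daily features

**HRVsd.** For each date d, HRVsd is the sample (n−1) standard deviation of
nightly lnRMSSD over the 7 calendar days strictly before d, defined when at
least 3 of those days are observed, missing otherwise. "Prior days" is read
literally as excluding the index day; `include_current=True` gives the
inclusive variant for sensitivity analysis. HRVsd is computed on the log
scale because all modelling is done on lnRMSSD. A rolling coefficient of
variation of raw RMSSD is available as an optional comparison column but is
deliberately not the primary statistic: within-subject trend analysis with a
level × dispersion interaction needs the two components separable, and a CV
folds part of the level trend into the dispersion metric.

**EMA day assignment.** The daily alcohol item is open 19:00–15:00 (next
day) to accommodate night shifts; a response belongs to the day its window
opened (boundaries inclusive on both ends; 15:00–19:00 is an error). Multiple
responses in one window: the last supersedes, with a warning. All times are
study-local wall clock; no timezone handling.

**Joining.** The daily table is a full outer join on (participant, date)
reindexed to each participant's continuous calendar range, so missing days
are present rows with missing fields; duplicate keys are rejected, never
silently aggregated.

## 3. Windows and trend slopes

Consecutive questionnaire dates cut each participant's daily series into
half-open windows [q_k, q_{k+1}) — the questionnaire day opens the window it
precedes, so no day is counted twice. Within a window each daily variable is
regressed on time with dates coded as integer days since window start;
missing days are omitted. The slope ("trend beta") has units of the variable
per day; since all model inputs are later standardized, the time unit does
not affect final coefficients. A variable with fewer than
`min_trend_obs = 10` observed days in a window yields a missing trend (a
guard against degenerate slopes; the appropriate minimum for a ~35-day
window is a judgement call, config-exposed). Windows with any missing trend
or change score are retained but flagged incomplete; the model layer then
drops them listwise.

The 4DSQ recalls the previous week, while the window's trends span its full
five weeks; no lag correction is applied — the change-score-vs-trend pairing
is used as-is, matching the design this pipeline implements.

## 4. Questionnaire scoring

Items recode no→0, sometimes→1, regularly/often/very_often→2 and sum per
scale (stress 16 items, anxiety 12, depression 5, somatisation 16 — these
published counts cover 49 of the instrument's 50 items, so the default map
leaves item 50 unassigned; a user-supplied item map with the same 16/12/5/16
composition is accepted). A scale with any missing item is unscorable
(missing, no pro-rating). Change scores are later-minus-earlier, positive =
increase. Clinical cut-offs are carried as reference constants only and play
no analytic role.

**Floor screening.** A scale is flagged when the fraction of zero scores
across all questionnaires reaches `floor_threshold = 0.8` (chosen below the
≥ 0.875 zero fractions typical of depression/anxiety in healthy occupational
samples, and far above anything a modellable scale shows). The regression
layer refuses flagged outcomes — with ~90% of scores at zero there is no
variance to model and any fit would be driven by a handful of points — unless
explicitly forced.

## 5. Association models

Standardization is at the grand mean over analysed (listwise-complete)
windows with the sample SD; means and SDs are retained for back-conversion.
The three steps are nested OLS fits (controls; + HRV and HRVsd trends;
+ their product). Choices worth stating:

* **Interaction term** = product of the standardized main-effect columns,
  not re-standardized after multiplication (standard moderated-regression
  practice).
* **ΔF** is reported as the difference of successive model F statistics —
  the convention that matches stepwise summary tables, and which can
  legitimately be negative — while the *p*-value for each step comparison
  comes from the conventional partial-F (nested model) test. Both are
  reported; they answer different questions.
* **Dependence.** Repeated windows within a participant are not modelled in
  the primary fit. With ~9 participants there is too little between-subject
  variance to support random slopes (such fits go singular); plain OLS is
  the parsimonious choice, with participant-clustered standard errors
  available as a default-off sensitivity variant.
* **Simple slopes.** At moderator value h, the conditional focal coefficient
  is β_hrvsd + h·β_int with variance v(β_hrvsd) + h²·v(β_int) + 2h·cov and a
  95% CI on the step-3 residual-df t distribution. This is algebraically
  identical to refitting with the moderator re-centred at h (a test asserts
  the equivalence).
* **Correlations** are pairwise-complete Pearson with two-sided p and
  0.05/0.01/0.001 stars.
* No multiple-testing correction is applied across outcomes; the per-outcome
  hierarchy is reported as-is.

## 6. Synthetic data generator

The generator emulates the study conditions the pipeline is sized for:
9 participants observed 15–55 weeks with a questionnaire every 35 days. The
default week allocation (15, 15, 15, 20, 25, 25, 25, 40, 55) spans that
range and yields exactly 47 five-week windows — the analysis sample size the
design targets. Defaults and what they represent:

| parameter | default | meaning |
|---|---|---|
| `baseline_ln_rmssd_mean` / `_sd` | 4.1 / 0.3 ln ms | between-person nightly lnRMSSD (~60 ms RMSSD, typical adult range) |
| `level_slope_sd` | 0.01 /day | per-window latent drift of the lnRMSSD level (±~0.35 over 5 weeks) |
| `dispersion_slope_sd` | 0.003 /day | per-window drift of the nightly SD σ(t) |
| `nightly_noise_sd` | 0.25 ln ms | within-person night-to-night variability at window start |
| `hrv_missing_rate` / `ema_missing_rate` | 0.057 / 0.11 | nightly HRV 94.3% and EMA 89.0% completeness targets |
| `gamma` | hrvsd 0.5, int −0.4, hrv −0.1, mvpa −0.2, tst 0.05, alcohol 0 | standardized outcome effects of the latent window slopes |
| `outcome_noise_sd` | 0.8 | residual SD of the standardized five-week change |
| `floor_zero_prob` | 0.9 | zero-inflation of depression/anxiety scores |

Nightly lnRMSSD is level(t) + N(0, σ(t)) with level and σ drifting linearly
at per-window latent slopes that carry over continuously across window
boundaries (σ truncated at `sigma_min = 0.02`). Linear-in-time σ is the
simplest mechanism that makes the realized 7-day rolling SD trend linearly —
i.e. exactly the quantity the window slope estimator measures.

Outcome changes are generated on the standardized scale,
Δ* = γᵀ(z_hrv, z_hrvsd, z_hrv·z_hrvsd, z_tst, z_mvpa, z_alc) + noise, where
z are the latent slopes divided by their population SDs, then mapped to
integer questionnaire scores by cumulative rounding of a latent score path
clipped to scale bounds (4 raw points per SD of change). Item-level
responses are then constructed to sum exactly to those scores, so the
scoring module is exercised end-to-end. Depression/anxiety are zero-inflated
counts, reproducing floor effects. An optional IBI-level mode
(`simulate_ibi_night`) synthesizes raw beat series from an AR(1) calibrated
to a target RMSSD, with injected ectopic beats, to exercise the per-night
pipeline; it is off by default because it is ~1000× more data per night.

**Two generation levels.** `simulate_cohort` produces the full daily
measurement chain; estimates recovered through it are attenuated relative to
γ (window slopes are estimated from ~35 noisy nights, classic
errors-in-variables — e.g. β̂_hrvsd ≈ 0.41 for γ_hrvsd = 0.5 at the default
noise). `simulate_window_sample` draws the standardized window-level design
directly and is the right tool for recovery and power experiments about the
*model layer* itself (there, β̂ recovers γ up to the ~2.5% shrinkage from
standardizing an outcome whose total variance slightly exceeds 1).

**What passing tests do and do not show.** The generator's missingness is
independent and identically distributed, nights are conditionally Gaussian,
and questionnaire changes depend on the latent slopes only — no ectopic-rate
drift, no weekend structure, no shift schedules, no feedback from symptoms to
behaviour. Tests passing on these cohorts validate the pipeline's
*computations*, not the substantive claim that real HRV-fluctuation trends
predict real stress changes.

## 7. Problem sizes and numerics

Experiment sizes used by the test suite: oracle equivalence on 1,000 random
nights of 60–220 beats; rolling-SD oracle on a 1,000-day series at 20%
missingness; 10,000 random scoring perturbations; 100 random designs for the
normal-equations check; 100 replicates of n = 500 windows for parameter
recovery; 200 replicates for the interaction-pattern experiment; the
end-to-end run uses the default 47-window cohort. These sizes make the Monte
Carlo error small relative to every asserted tolerance while keeping the
whole suite fast on one CPU.

Numerical choices: trend slopes use the centred closed form
Σ(x−x̄)(y−ȳ)/Σ(x−x̄)²; OLS fits go through statsmodels (QR-based); designs
are rank-checked before fitting; standardization requires nonzero SD and at
least 3 complete windows; model fitting requires n > step-3 terms + 1.
Determinism: every random quantity flows from one integer seed via
per-participant `SeedSequence` substreams, and pipeline outputs (CSV, JSON,
PNG) are byte-identical across reruns with the same config.

## 8. Known limitations

* The artifact-screening constants and segment-validity thresholds are
  plausible conventions, not the (unpublished) device values; nightly RMSSD
  from this pipeline will not numerically match a vendor's output.
* OLS on nested windows understates standard errors if between-subject
  variance is non-negligible; the cluster-robust variant exists but small
  cluster counts (~9) make robust SEs themselves unstable.
* The floor screen is a blunt zero-fraction rule; zero-inflated outcome
  models are out of scope by design.
* Trend betas assume linear within-window change; no robust or nonlinear
  trend estimators, no changepoint detection.
* The synthetic generator is a testbed, not a calibrated digital twin (see
  §6); effect-size defaults are chosen for testability of direction and
  magnitude recovery, not fidelity to any real cohort.
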