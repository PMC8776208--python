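"""Moderated hierarchical regression linking trend betas to outcome change.

The unit of analysis is the five-week observation window.  All analysed
variables — the four questionnaire change scores and the five daily trend
betas — are standardized at the grand mean (z = (x − mean) / SD over all
analysed windows), which removes the per-day slope units and makes the
regression coefficients comparable across variables.

Each outcome is then fit by a three-step nested OLS hierarchy:

* step 1 — control trends only: TST, MVPA, alcohol;
* step 2 — adds the main effects: HRV trend and HRVsd trend;
* step 3 — adds the HRV × HRVsd interaction (product of the standardized
  main-effect columns).

Per step the coefficient table, R², adjusted R², model F and p are reported;
between consecutive steps ΔR², ΔF and a partial-F comparison p.  The ΔF rows
are reported as differences of successive model F statistics (so they can be
negative); the comparison p-values come from the conventional partial-F test.

The interaction is probed with simple slopes: the conditional HRVsd
coefficient β_hrvsd + h·β_int at moderator values h (HRV trend, standardized),
with delta-method standard errors and t-based confidence intervals.  A
declining conditional slope with rising h is the buffering pattern: an HRV
uptrend undoes the association between HRV-fluctuation uptrend and symptom
increase.

Window-to-window dependence within participants is ignored in the primary
fit; a cluster-robust standard-error variant is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .trend_windows import CHANGE_COLUMNS, TREND_COLUMNS

logger = logging.getLogger(__name__)

PREDICTOR_STEPS = {
    1: ["tst_uptrend", "mvpa_uptrend", "alcohol_uptrend"],
    2: ["tst_uptrend", "mvpa_uptrend", "alcohol_uptrend", "hrv_uptrend", "hrvsd_uptrend"],
}
INTERACTION = "hrv_x_hrvsd"
MODERATOR = "hrv_uptrend"
FOCAL = "hrvsd_uptrend"

DEFAULT_VARIABLES = CHANGE_COLUMNS + TREND_COLUMNS


class FloorEffectRefusal(RuntimeError):
    """Raised when modelling is requested for a floor-flagged outcome."""


@dataclass(frozen=True)
class StandardizedSample:
    """Listwise-complete window matrix, standardized at the grand mean."""

    data: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    n_dropped: int

    @property
    def n(self) -> int:
        return len(self.data)


@dataclass
class StepFit:
    step: int
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    f_stat: float
    f_pvalue: float
    df_resid: float
    result: object = field(repr=False, default=None)  # statsmodels results


@dataclass
class HierarchicalFit:
    outcome: str
    steps: list[StepFit]
    delta_r2: dict[int, float]        # step -> R²_k − R²_{k−1}
    delta_f: dict[int, float]         # step -> F_k − F_{k−1}
    comparison_p: dict[int, float]    # step -> partial-F test p vs previous step

    def step3(self) -> StepFit:
        return self.steps[-1]


@dataclass(frozen=True)
class SimpleSlopeProfile:
    """Conditional HRVsd coefficient across a grid of moderator values."""

    moderator: np.ndarray
    slope: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    df_resid: float


def standardize(
    windows: pd.DataFrame, variables: list[str] | None = None
) -> StandardizedSample:
    """Grand-mean standardization with listwise deletion.

    Windows with a missing value on any requested variable are excluded
    (and logged); each remaining column becomes (x − grand mean) / grand SD
    with the sample (n − 1) SD.  Means and SDs are retained so model output
    can be mapped back to raw units.
    """
    variables = list(variables if variables is not None else DEFAULT_VARIABLES)
    subset = windows[variables].apply(pd.to_numeric)
    complete = subset.dropna()
    n_dropped = len(subset) - len(complete)
    if n_dropped:
        logger.info("standardize: %d incomplete windows excluded listwise", n_dropped)
    if len(complete) < 3:
        raise ValueError("at least 3 complete windows required")
    sds = complete.std(ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"zero-SD variable(s): {list(zero.index)}")
    means = complete.mean()
    z = (complete - means) / sds
    keep_cols = [c for c in windows.columns if c not in variables]
    data = pd.concat([windows.loc[complete.index, keep_cols], z], axis=1).reset_index(drop=True)
    return StandardizedSample(data=data, means=means, sds=sds, n_dropped=n_dropped)


def _fit_step(y: pd.Series, X: pd.DataFrame, step: int, cluster: pd.Series | None) -> StepFit:
    Xc = sm.add_constant(X, has_constant="add")
    if cluster is not None:
        res = sm.OLS(y, Xc).fit(cov_type="cluster", cov_kwds={"groups": cluster})
    else:
        res = sm.OLS(y, Xc).fit()
    return StepFit(
        step=step,
        terms=list(X.columns),
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df_resid=float(res.df_resid),
        result=res,
    )


def fit_hierarchical(
    sample: StandardizedSample,
    outcome: str,
    floor_flagged: bool = False,
    force: bool = False,
    cluster_robust: bool = False,
) -> HierarchicalFit:
    """Fit the three nested OLS steps for one outcome.

    Refuses a floor-flagged outcome unless ``force`` is set: with nearly all
    scores at zero no model can be formed that could detect an association.
    ``cluster_robust`` switches to participant-clustered standard errors
    (sensitivity variant; the primary fit ignores the nesting).
    """
    if floor_flagged and not force:
        raise FloorEffectRefusal(
            f"outcome {outcome!r} is floor-flagged: no models could be formed "
            "(pass force=True to override)"
        )
    df = sample.data
    n = len(df)
    if n <= 7 + 1:
        raise ValueError(f"too few windows (n={n}) for the step-3 term count")
    y = df[outcome]
    cluster = df["participant_id"] if cluster_robust and "participant_id" in df else None

    X3 = df[PREDICTOR_STEPS[2]].copy()
    X3[INTERACTION] = df[MODERATOR] * df[FOCAL]
    designs = {1: df[PREDICTOR_STEPS[1]], 2: df[PREDICTOR_STEPS[2]], 3: X3}
    for step, X in designs.items():
        rank = np.linalg.matrix_rank(sm.add_constant(X, has_constant="add").to_numpy())
        if rank < X.shape[1] + 1:
            raise ValueError(f"rank-deficient design at step {step}")

    steps = [_fit_step(y, X, k, cluster) for k, X in designs.items()]
    delta_r2, delta_f, comparison_p = {}, {}, {}
    for prev, cur in zip(steps, steps[1:]):
        delta_r2[cur.step] = cur.r2 - prev.r2
        delta_f[cur.step] = cur.f_stat - prev.f_stat
        f_cmp, p_cmp, _ = cur.result.compare_f_test(prev.result)
        comparison_p[cur.step] = float(p_cmp)
    return HierarchicalFit(outcome, steps, delta_r2, delta_f, comparison_p)


def simple_slopes(
    fit: HierarchicalFit, moderator_grid: np.ndarray | None = None
) -> SimpleSlopeProfile:
    """Conditional HRVsd coefficient along a grid of HRV-trend values.

    At moderator value h the conditional slope is β_hrvsd + h·β_int with
    variance var(β_hrvsd) + h²·var(β_int) + 2h·cov, and a 95% CI from the t
    distribution on the step-3 residual degrees of freedom.  Equivalent to
    refitting the step-3 model with the moderator re-centred at h.
    """
    step3 = fit.step3()
    if step3.result is None:
        raise ValueError("step-3 fit with coefficient covariance required")
    if moderator_grid is None:
        moderator_grid = np.linspace(-2.0, 2.0, 41)
    h = np.asarray(moderator_grid, dtype=float)

    cov = step3.result.cov_params()
    b_sd = float(step3.params[FOCAL])
    b_int = float(step3.params[INTERACTION])
    v_sd = float(cov.loc[FOCAL, FOCAL])
    v_int = float(cov.loc[INTERACTION, INTERACTION])
    c = float(cov.loc[FOCAL, INTERACTION])

    slope = b_sd + h * b_int
    se = np.sqrt(v_sd + h * h * v_int + 2.0 * h * c)
    tcrit = scipy.stats.t.ppf(0.975, step3.df_resid)
    return SimpleSlopeProfile(
        moderator=h,
        slope=slope,
        se=se,
        ci_low=slope - tcrit * se,
        ci_high=slope + tcrit * se,
        df_resid=step3.df_resid,
    )


def correlation_table(
    sample: StandardizedSample | pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations with significance stars.

    Returns a long-format table (var_a, var_b, r, p, stars, n) over the lower
    triangle; stars mark two-sided p < 0.05 / 0.01 / 0.001.
    """
    df = sample.data if isinstance(sample, StandardizedSample) else sample
    variables = list(variables if variables is not None else
                     [c for c in DEFAULT_VARIABLES if c in df.columns])
    rows = []
    for i, a in enumerate(variables):
        for b in variables[:i]:
            pair = df[[a, b]].apply(pd.to_numeric).dropna()
            if len(pair) < 3:
                r, p = float("nan"), float("nan")
            else:
                r, p = scipy.stats.pearsonr(pair[a], pair[b])
            rows.append(
                {"var_a": a, "var_b": b, "r": float(r), "p": float(p),
                 "stars": _stars(p), "n": len(pair)}
            )
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Tabular / file output


def fit_summary_table(fit: HierarchicalFit) -> pd.DataFrame:
    """Per-step coefficient table in the conventional stacked layout."""
    rows = []
    for step in fit.steps:
        for term in ["const"] + step.terms:
            rows.append(
                {
                    "step": step.step,
                    "term": "intercept" if term == "const" else term,
                    "beta": float(step.params[term]),
                    "se": float(step.bse[term]),
                    "p": float(step.pvalues[term]),
                }
            )
    return pd.DataFrame(rows)


def fit_summary_dict(fit: HierarchicalFit) -> dict:
    """Model-level statistics (R², adjusted R², F, ΔR², ΔF, p) as JSON-ready dict."""
    out: dict = {"outcome": fit.outcome, "steps": {}}
    for step in fit.steps:
        out["steps"][str(step.step)] = {
            "r2": step.r2,
            "adj_r2": step.adj_r2,
            "f": step.f_stat,
            "f_pvalue": step.f_pvalue,
            "delta_r2": fit.delta_r2.get(step.step),
            "delta_f": fit.delta_f.get(step.step),
            "comparison_p": fit.comparison_p.get(step.step),
        }
    return out


def simple_slope_table(profile: SimpleSlopeProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "hrv_uptrend_z": profile.moderator,
            "conditional_hrvsd_beta": profile.slope,
            "se": profile.se,
            "ci_low": profile.ci_low,
            "ci_high": profile.ci_high,
        }
    )


def scatter_plot(sample: StandardizedSample, outcome: str, path=None):
    """Outcome vs HRVsd-trend scatter with OLS fit line and 95% CI band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = sample.data[FOCAL].to_numpy(float)
    y = sample.data[outcome].to_numpy(float)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    grid = np.linspace(x.min(), x.max(), 100)
    pred = res.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, color="black", s=18)
    ax.plot(grid, pred["mean"], color="black", lw=2)
    ax.fill_between(grid, pred["mean_ci_lower"], pred["mean_ci_upper"], color="grey", alpha=0.4)
    ax.set_xlabel("HRVsd uptrend (z)")
    ax.set_ylabel(f"{outcome} (z)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def interaction_plot(profile: SimpleSlopeProfile, outcome: str, path=None):
    """Conditional-coefficient curve by moderator with 95% CI band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(profile.moderator, profile.slope, color="black", lw=2)
    ax.fill_between(profile.moderator, profile.ci_low, profile.ci_high, color="grey", alpha=0.4)
    ax.axhline(0.0, color="black", lw=0.8, ls="--")
    ax.set_xlabel("HRV uptrend (z)")
    ax.set_ylabel(f"conditional HRVsd coefficient on {outcome}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
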