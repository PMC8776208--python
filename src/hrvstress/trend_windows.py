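"""Between-questionnaire observation windows and per-window trend slopes.

Each participant's daily table is cut into consecutive half-open windows
[q_k, q_{k+1}) bounded by questionnaire dates (nominally five weeks apart).
Within a window, each daily variable — lnRMSSD, HRVsd, total sleep time,
MVPA, alcohol — is regressed on time, with dates coded as integer days since
the window start; the OLS slope ("trend beta", units per day) summarises the
variable's drift over the window.  A positive beta is an uptrend.  Missing
days are simply omitted; a variable observed on fewer than ``min_trend_obs``
days in a window yields a missing trend.

One window plus its questionnaire change scores forms the unit of analysis
consumed by the association models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date

import numpy as np
import pandas as pd

from .questionnaire import SCALES, ChangeScores, FourDSQScores, change_scores

logger = logging.getLogger(__name__)

DEFAULT_MIN_TREND_OBS = 10

#: Daily variable → trend-beta column name.
TREND_VARIABLES = {
    "ln_rmssd": "hrv_uptrend",
    "hrv_sd": "hrvsd_uptrend",
    "tst_min": "tst_uptrend",
    "mvpa_min": "mvpa_uptrend",
    "alcohol": "alcohol_uptrend",
}
TREND_COLUMNS = list(TREND_VARIABLES.values())
CHANGE_COLUMNS = [f"{s}_increase" for s in SCALES]


@dataclass(frozen=True)
class ObservationWindow:
    """One five-week unit of analysis: change scores plus five trend betas."""

    participant_id: str
    start_date: Date
    end_date: Date
    change: ChangeScores
    trends: dict[str, float]          # NaN where a trend could not be formed
    n_days_used: dict[str, int]

    @property
    def incomplete(self) -> bool:
        missing_trend = any(not np.isfinite(v) for v in self.trends.values())
        missing_change = any(v is None for v in self.change.as_dict().values())
        return missing_trend or missing_change


def window_slices(
    daily: pd.DataFrame, questionnaire_dates: list[Date]
) -> list[tuple[Date, Date, pd.DataFrame]]:
    """Slice one participant's daily table into half-open windows.

    Window k holds days d with date(k) <= d < date(k+1); a day after the last
    questionnaire belongs to no window.  Questionnaire dates must be sorted
    and distinct.
    """
    if len(questionnaire_dates) < 2:
        raise ValueError("at least two questionnaire dates required")
    if any(b <= a for a, b in zip(questionnaire_dates, questionnaire_dates[1:])):
        raise ValueError("questionnaire dates must be sorted and distinct")
    dates = pd.to_datetime(daily["date"]).dt.date
    out = []
    for start, end in zip(questionnaire_dates, questionnaire_dates[1:]):
        mask = (dates >= start) & (dates < end)
        out.append((start, end, daily.loc[mask]))
    return out


def trend_beta(
    dates: pd.Series | np.ndarray,
    values: pd.Series | np.ndarray,
    min_trend_obs: int = DEFAULT_MIN_TREND_OBS,
    origin: Date | None = None,
) -> tuple[float, int]:
    """OLS slope of a daily variable on time, in variable units per day.

    Dates are coded as integer days since ``origin`` (default: the first
    date supplied); missing values are omitted.  Returns ``(slope, n_used)``;
    the slope is NaN (with a warning) when fewer than ``min_trend_obs``
    non-missing days remain, and a zero-variance time axis raises.
    """
    d = pd.to_datetime(pd.Series(np.asarray(dates)))
    y = pd.to_numeric(pd.Series(np.asarray(values, dtype=float)))
    keep = y.notna().to_numpy()
    d, y = d[keep], y[keep]
    n = int(keep.sum())
    if n < min_trend_obs:
        logger.warning("trend skipped: %d observed days < min_trend_obs=%d", n, min_trend_obs)
        return float("nan"), n
    start = pd.Timestamp(origin) if origin is not None else d.iloc[0]
    x = (d - start).dt.days.to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero date variance: all observations on one day")
    xc = x - x.mean()
    slope = float(np.dot(xc, y.to_numpy() - y.mean()) / np.dot(xc, xc))
    return slope, n


def assemble_windows(
    daily: pd.DataFrame,
    questionnaires: dict[str, list[FourDSQScores]],
    min_trend_obs: int = DEFAULT_MIN_TREND_OBS,
) -> list[ObservationWindow]:
    """Build every participant's observation windows.

    ``questionnaires`` maps participant id to that participant's scored
    questionnaires; each consecutive pair yields one window holding the
    change scores and the five trend betas.  Windows with any missing trend
    or change are retained and flagged incomplete rather than dropped.
    """
    windows: list[ObservationWindow] = []
    for pid in sorted(questionnaires):
        scored = sorted(questionnaires[pid], key=lambda s: s.date)
        part_daily = daily[daily["participant_id"] == pid]
        q_dates = [s.date for s in scored]
        slices = window_slices(part_daily, q_dates) if len(q_dates) >= 2 else []
        for (start, end, subset), earlier, later in zip(slices, scored, scored[1:]):
            trends: dict[str, float] = {}
            n_used: dict[str, int] = {}
            for var, name in TREND_VARIABLES.items():
                if subset.empty or var not in subset:
                    trends[name], n_used[name] = float("nan"), 0
                    continue
                slope, n = trend_beta(
                    subset["date"], subset[var], min_trend_obs, origin=start
                )
                trends[name], n_used[name] = slope, n
            windows.append(
                ObservationWindow(
                    participant_id=pid,
                    start_date=start,
                    end_date=end,
                    change=change_scores(earlier, later),
                    trends=trends,
                    n_days_used=n_used,
                )
            )
    return windows


def windows_table(windows: list[ObservationWindow]) -> pd.DataFrame:
    """Flatten ObservationWindows into the ``windows.csv`` schema."""
    rows = []
    for w in windows:
        row: dict[str, object] = {
            "participant_id": w.participant_id,
            "start_date": w.start_date.isoformat(),
            "end_date": w.end_date.isoformat(),
        }
        for k, v in w.change.as_dict().items():
            row[k] = np.nan if v is None else v
        row.update(w.trends)
        for name, n in w.n_days_used.items():
            row[f"n_days_{name}"] = n
        row["incomplete"] = w.incomplete
        rows.append(row)
    return pd.DataFrame(rows)
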