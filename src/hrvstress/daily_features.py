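"""Per-participant daily feature table.

Joins nightly lnRMSSD, wearable activity summaries (total sleep time, minutes
of moderate-to-vigorous physical activity), and the daily alcohol EMA
(ecological momentary assessment) into one row per participant per calendar
day, then derives the day-to-day HRV fluctuation statistic: the rolling
standard deviation of nightly lnRMSSD over the prior days (HRVsd).

The EMA item is open from 19:00 to 15:00 the next day so that night-shift
workers can answer after a shift; a response is attributed to the day on
which the window opened.
"""

from __future__ import annotations

import logging
from datetime import date as Date
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_DAYS = 7
DEFAULT_MIN_OBS = 3

EMA_OPEN = time(19, 0)
EMA_CLOSE = time(15, 0)

DAILY_COLUMNS = ["participant_id", "date", "ln_rmssd", "hrv_sd", "tst_min", "mvpa_min", "alcohol"]


class EMAWindowError(ValueError):
    """Raised for a response timestamp outside the 19:00–15:00 EMA window."""


class DuplicateKeyError(ValueError):
    """Raised when an input carries duplicate (participant, date) keys."""


def rolling_sd(
    ln_rmssd: pd.Series,
    window_days: int = DEFAULT_WINDOW_DAYS,
    min_obs: int = DEFAULT_MIN_OBS,
    include_current: bool = False,
) -> pd.Series:
    """Rolling standard deviation of nightly lnRMSSD over the prior days.

    For each date d the window holds the ``window_days`` calendar days ending
    at d − 1 ("prior days"; set ``include_current`` to end the window at d
    instead, a sensitivity variant).  The value is the sample (n − 1) standard
    deviation of the non-missing lnRMSSD values in the window when at least
    ``min_obs`` of them are observed, and missing otherwise.  Missingness
    propagates; this never raises on gaps.

    Parameters
    ----------
    ln_rmssd : pandas.Series
        Indexed by datetime-like calendar date; may contain NaN.
    """
    if window_days < 2:
        raise ValueError("window_days must be >= 2")
    if not 1 < min_obs <= window_days:
        raise ValueError("min_obs must satisfy 1 < min_obs <= window_days")

    s = ln_rmssd.copy()
    s.index = pd.DatetimeIndex(s.index)
    full = pd.date_range(s.index.min(), s.index.max(), freq="D")
    s = s.reindex(full)
    base = s if include_current else s.shift(1)
    out = base.rolling(window=window_days, min_periods=min_obs).std(ddof=1)
    return out.reindex(pd.DatetimeIndex(ln_rmssd.index))


def assign_ema_day(response_timestamp: datetime) -> Date:
    """Map an EMA response timestamp to the study day it reports on.

    The daily alcohol item opens at 19:00 and closes at 15:00 the next day;
    the response belongs to the day the window opened.  A timestamp at or
    after 19:00 maps to its own date; one at or before 15:00 maps to the
    previous date; anything strictly between 15:00 and 19:00 is outside every
    window and is an error.
    """
    t = response_timestamp.time()
    d = response_timestamp.date()
    if t >= EMA_OPEN:
        return d
    if t <= EMA_CLOSE:
        return d - timedelta(days=1)
    raise EMAWindowError(f"timestamp {response_timestamp} outside EMA window")


def _check_unique(df: pd.DataFrame, keys: list[str], name: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        first = df.loc[dup, keys].iloc[0].tolist()
        raise DuplicateKeyError(f"duplicate key {tuple(first)} in {name}")


def collapse_ema(ema: pd.DataFrame) -> pd.DataFrame:
    """Assign each EMA response to its study day and collapse duplicates.

    Input columns: participant_id, timestamp (datetime-like), drinks.  When a
    participant answered more than once within one window the last response
    supersedes the earlier ones (a warning is logged).  Returns columns
    participant_id, date, alcohol.
    """
    if ema.empty:
        return pd.DataFrame(columns=["participant_id", "date", "alcohol"])
    ema = ema.copy()
    ts = pd.to_datetime(ema["timestamp"])
    ema["date"] = [assign_ema_day(t.to_pydatetime()) for t in ts]
    ema["_ts"] = ts
    n_dup = ema.duplicated(subset=["participant_id", "date"]).sum()
    if n_dup:
        logger.warning("%d EMA responses superseded by a later response in the same window", n_dup)
    ema = ema.sort_values("_ts").drop_duplicates(subset=["participant_id", "date"], keep="last")
    out = ema[["participant_id", "date", "drinks"]].rename(columns={"drinks": "alcohol"})
    return out.reset_index(drop=True)


def build_daily_table(
    nightly_hrv: pd.DataFrame,
    ema: pd.DataFrame | None = None,
    activity: pd.DataFrame | None = None,
    window_days: int = DEFAULT_WINDOW_DAYS,
    min_obs: int = DEFAULT_MIN_OBS,
    include_current: bool = False,
    add_cv: bool = False,
) -> pd.DataFrame:
    """Build the continuous per-participant daily table.

    Full-outer join of nightly HRV, collapsed EMA and activity on
    (participant, date), reindexed to each participant's continuous calendar
    range (missing days are present with missing fields), with HRVsd derived
    afterwards.  Duplicate keys in any input are rejected.

    ``add_cv`` additionally emits ``hrv_cv``, a rolling coefficient of
    variation of raw RMSSD over the same window — provided only for
    comparison; the fluctuation statistic used by the analysis is ``hrv_sd``
    on the log scale, which keeps level and dispersion trends separable.
    """
    hrv = nightly_hrv.copy()
    hrv["date"] = pd.to_datetime(hrv["night_date"]).dt.date
    _check_unique(hrv, ["participant_id", "date"], "nightly_hrv")
    parts = [hrv[["participant_id", "date", "ln_rmssd"]]]
    if add_cv:
        parts[0] = hrv[["participant_id", "date", "ln_rmssd", "rmssd_ms"]]

    if ema is not None and not ema.empty:
        ema_daily = collapse_ema(ema)
        parts.append(ema_daily)
    else:
        parts.append(pd.DataFrame(columns=["participant_id", "date", "alcohol"]))

    if activity is not None and not activity.empty:
        act = activity.copy()
        act["date"] = pd.to_datetime(act["date"]).dt.date
        _check_unique(act, ["participant_id", "date"], "activity")
        parts.append(act[["participant_id", "date", "tst_min", "mvpa_min"]])
    else:
        parts.append(pd.DataFrame(columns=["participant_id", "date", "tst_min", "mvpa_min"]))

    merged = parts[0]
    for p in parts[1:]:
        merged = merged.merge(p, on=["participant_id", "date"], how="outer")

    out_frames = []
    for pid, grp in merged.groupby("participant_id", sort=True):
        grp = grp.set_index(pd.DatetimeIndex(pd.to_datetime(grp["date"]))).sort_index()
        full = pd.date_range(grp.index.min(), grp.index.max(), freq="D")
        grp = grp.reindex(full)
        grp["participant_id"] = pid
        grp["date"] = full.date
        grp["hrv_sd"] = rolling_sd(grp["ln_rmssd"], window_days, min_obs, include_current)
        if add_cv:
            r = grp["rmssd_ms"]
            base = r if include_current else r.shift(1)
            roll = base.rolling(window=window_days, min_periods=min_obs)
            grp["hrv_cv"] = roll.std(ddof=1) / roll.mean()
            grp = grp.drop(columns=["rmssd_ms"])
        out_frames.append(grp.reset_index(drop=True))

    cols = DAILY_COLUMNS + (["hrv_cv"] if add_cv else [])
    out = pd.concat(out_frames, ignore_index=True)[cols]
    for c in ("ln_rmssd", "hrv_sd", "tst_min", "mvpa_min", "alcohol"):
        out[c] = pd.to_numeric(out[c])
    return out
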