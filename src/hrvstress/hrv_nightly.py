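"""Nightly RMSSD from raw inter-beat intervals.

A night of photoplethysmography-derived inter-beat intervals (IBIs) is turned
into one nightly heart-rate-variability value in three steps, mirroring the
on-device processing of ring-type wearables:

1. each IBI is labelled normal or abnormal by its relative deviation from the
   median of its nearest surrounding IBIs (ectopic-beat / artifact screening);
2. the night is tiled into contiguous 5-minute segments;
3. RMSSD (root mean square of successive differences, ms) is computed per
   segment from the normal-labelled IBIs, and segments with sufficient valid
   data are averaged into the nightly RMSSD, which is then log-transformed
   (lnRMSSD) for downstream modelling.

A night whose every segment fails the validity thresholds, or whose RMSSD is
exactly zero (physiologically implausible; a sensor-failure signature), yields
a missing value rather than an exception: downstream code treats it as a
missing-HRV day.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default artifact-screening parameters.  The neighbourhood size and relative
#: threshold of proprietary on-device filters are not published; 5 neighbours
#: and a 30% deviation bound are a conventional ectopic-beat screening choice.
DEFAULT_NEIGHBORHOOD = 5
DEFAULT_REL_THRESHOLD = 0.30

DEFAULT_SEGMENT_MINUTES = 5
DEFAULT_MIN_VALID_FRACTION = 0.5
DEFAULT_MIN_NORMAL_IBIS = 30


class EmptySeriesError(ValueError):
    """Raised when a night contains no intervals."""


@dataclass(frozen=True)
class NightIBISeries:
    """One night of inter-beat intervals for one participant.

    Parameters
    ----------
    participant_id : str
        Opaque participant identifier.
    night_date : datetime.date
        Date of sleep onset.
    timestamps : ndarray of float
        Seconds from night start, strictly increasing.
    intervals_ms : ndarray of float
        Inter-beat intervals in milliseconds, all positive.
    """

    participant_id: str
    night_date: Date
    timestamps: np.ndarray
    intervals_ms: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        ibi = np.asarray(self.intervals_ms, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "intervals_ms", ibi)
        if ts.shape != ibi.shape:
            raise ValueError("timestamps and intervals must have equal length")
        if ts.size and np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(ibi <= 0):
            raise ValueError("every interval_ms must be positive")

    def __len__(self) -> int:
        return int(self.intervals_ms.size)


@dataclass(frozen=True)
class Segment:
    """One fixed-length slice of a night: its normal IBIs and validity."""

    index: int
    normal_ibis: np.ndarray
    n_total: int

    @property
    def n_normal(self) -> int:
        return int(self.normal_ibis.size)

    @property
    def valid_fraction(self) -> float:
        """Normal IBIs over total IBIs in the segment; 0.0 if empty."""
        return self.n_normal / self.n_total if self.n_total else 0.0


@dataclass(frozen=True)
class NightHRV:
    """Nightly HRV summary.  ``rmssd_ms``/``ln_rmssd`` are NaN when missing."""

    participant_id: str
    night_date: Date
    rmssd_ms: float
    ln_rmssd: float
    n_valid_segments: int
    n_total_segments: int

    @property
    def is_missing(self) -> bool:
        return not math.isfinite(self.ln_rmssd)


def flag_artifacts(
    series: NightIBISeries,
    neighborhood: int = DEFAULT_NEIGHBORHOOD,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
) -> np.ndarray:
    """Label each IBI normal (True) or abnormal (False).

    An IBI is abnormal iff its absolute deviation from the median of its
    nearest ``neighborhood`` surrounding IBIs (itself excluded) exceeds
    ``rel_threshold`` times that median.  Near the edges of the night, where
    fewer than two neighbours are available on one side, all available
    neighbours are used.  Neighbours at equal index distance are resolved
    toward the earlier beat so the rule is deterministic.

    Returns
    -------
    ndarray of bool
        True where the IBI is labelled normal.
    """
    if len(series) == 0:
        raise EmptySeriesError("no intervals")
    if neighborhood < 2:
        raise ValueError("neighborhood must be >= 2")
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in (0, 1)")

    ibi = series.intervals_ms
    n = ibi.size
    normal = np.ones(n, dtype=bool)
    for i in range(n):
        med = np.median(_neighbor_values(ibi, i, neighborhood))
        if abs(ibi[i] - med) / med > rel_threshold:
            normal[i] = False
    return normal


def _neighbor_values(ibi: np.ndarray, i: int, k: int) -> np.ndarray:
    """The k nearest neighbours of index i (ties broken toward earlier beats)."""
    n = ibi.size
    if n == 1:
        # degenerate single-beat night: the beat is its own reference
        return ibi[[0]]
    lo, hi = max(0, i - k), min(n, i + k + 1)
    order = sorted((j for j in range(lo, hi) if j != i), key=lambda j: (abs(j - i), j))
    return ibi[order[:k]]


def segment_night(
    series: NightIBISeries,
    normal: np.ndarray,
    segment_minutes: int = DEFAULT_SEGMENT_MINUTES,
) -> list[Segment]:
    """Tile the night into contiguous fixed-length segments by timestamp.

    Segments tile ``[0, night end)`` in non-overlapping ``segment_minutes``
    windows; an IBI with timestamp t lands in segment ``floor(t / width)``.
    The trailing segment may be partial.  Each segment keeps only its
    normal-labelled IBIs plus the bookkeeping needed for the validity rule.
    """
    if segment_minutes < 1:
        raise ValueError("segment_minutes must be >= 1")
    normal = np.asarray(normal, dtype=bool)
    if normal.shape != series.intervals_ms.shape:
        raise ValueError("one label per IBI required")

    width = segment_minutes * 60.0
    seg_idx = np.floor(series.timestamps / width).astype(int)
    n_segments = int(seg_idx.max()) + 1 if len(series) else 0
    segments = []
    for s in range(n_segments):
        in_seg = seg_idx == s
        segments.append(
            Segment(
                index=s,
                normal_ibis=series.intervals_ms[in_seg & normal],
                n_total=int(in_seg.sum()),
            )
        )
    return segments


def rmssd(intervals_ms: np.ndarray) -> float:
    """Root mean square of successive differences, in ms.

    NaN when fewer than two intervals are available (no successive pairs).
    """
    x = np.asarray(intervals_ms, dtype=float)
    if x.size < 2:
        return float("nan")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def nightly_rmssd(
    segments: Sequence[Segment],
    participant_id: str,
    night_date: Date,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
    min_normal_ibis: int = DEFAULT_MIN_NORMAL_IBIS,
) -> NightHRV:
    """Average segment RMSSDs into one nightly value.

    A segment contributes iff its valid fraction is at least
    ``min_valid_fraction`` and it retains at least ``min_normal_ibis`` normal
    IBIs.  The nightly RMSSD is the unweighted arithmetic mean of the
    contributing segments' RMSSDs; lnRMSSD is its natural log.  With zero
    contributing segments, or a nightly RMSSD of exactly zero, the night is
    returned as missing (NaN fields) rather than raising.
    """
    if not segments:
        raise ValueError("at least one segment required")

    seg_values = [
        rmssd(seg.normal_ibis)
        for seg in segments
        if seg.valid_fraction >= min_valid_fraction and seg.n_normal >= min_normal_ibis
    ]
    seg_values = [v for v in seg_values if math.isfinite(v)]

    if not seg_values:
        return NightHRV(participant_id, night_date, float("nan"), float("nan"), 0, len(segments))

    value = float(np.mean(seg_values))
    if value == 0.0:
        logger.warning(
            "night %s/%s: zero RMSSD (constant IBIs); treating as missing",
            participant_id,
            night_date,
        )
        ln_value = float("nan")
    else:
        ln_value = math.log(value)
    return NightHRV(
        participant_id,
        night_date,
        value if value > 0.0 else float("nan"),
        ln_value,
        len(seg_values),
        len(segments),
    )


def process_night(
    series: NightIBISeries,
    neighborhood: int = DEFAULT_NEIGHBORHOOD,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    segment_minutes: int = DEFAULT_SEGMENT_MINUTES,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
    min_normal_ibis: int = DEFAULT_MIN_NORMAL_IBIS,
) -> NightHRV:
    """Full per-night pipeline: flag → segment → nightly RMSSD."""
    normal = flag_artifacts(series, neighborhood, rel_threshold)
    segments = segment_night(series, normal, segment_minutes)
    return nightly_rmssd(
        segments,
        series.participant_id,
        series.night_date,
        min_valid_fraction,
        min_normal_ibis,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_ibi_csv(path: str | Path) -> list[NightIBISeries]:
    """Read ``ibi.csv`` (participant_id, night_date, t_seconds, ibi_ms)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "night_date", "t_seconds", "ibi_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ibi.csv missing columns: {sorted(missing)}")
    out = []
    for (pid, night), grp in df.groupby(["participant_id", "night_date"], sort=True):
        grp = grp.sort_values("t_seconds")
        out.append(
            NightIBISeries(
                participant_id=str(pid),
                night_date=pd.Timestamp(night).date(),
                timestamps=grp["t_seconds"].to_numpy(float),
                intervals_ms=grp["ibi_ms"].to_numpy(float),
            )
        )
    return out


def nightly_table(nights: Sequence[NightHRV]) -> pd.DataFrame:
    """Assemble NightHRV records into the ``nightly_hrv.csv`` schema."""
    return pd.DataFrame(
        {
            "participant_id": [n.participant_id for n in nights],
            "night_date": [n.night_date.isoformat() for n in nights],
            "rmssd_ms": [n.rmssd_ms for n in nights],
            "ln_rmssd": [n.ln_rmssd for n in nights],
            "n_valid_segments": [n.n_valid_segments for n in nights],
            "n_total_segments": [n.n_total_segments for n in nights],
        }
    )
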