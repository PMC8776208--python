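"""Four-Dimensional Symptom Questionnaire (4DSQ) scoring.

The 4DSQ is a 50-item self-report instrument covering four symptom
dimensions: stress (16 items, 0–32), anxiety (12 items, 0–24), depression
(5 items, 0–10) and somatisation (16 items, 0–32).  Items ask about symptom
occurrence over the previous week on a five-point frequency scale and are
recoded 0 ('no'), 1 ('sometimes') or 2 ('regularly' / 'often' /
'very_often') before summing per scale.

This module also computes between-questionnaire change scores (later minus
earlier, so positive means an increase in the measured concept) and screens
scales for floor effects: when nearly all scores sit at zero there is no
variance left to model, and downstream regression refuses the outcome.

Those published item counts sum to 49 of the instrument's 50 items; the
default item-to-scale map below therefore leaves one item unassigned and is
replaceable by a user-supplied mapping keyed by item index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SCALES = ("stress", "anxiety", "depression", "somatisation")

#: Items per scale and the implied score maxima (2 × item count).
SCALE_ITEM_COUNTS = {"stress": 16, "anxiety": 12, "depression": 5, "somatisation": 16}
SCALE_MAXIMA = {scale: 2 * n for scale, n in SCALE_ITEM_COUNTS.items()}

#: Response categories and their recoded values.
CATEGORY_SCORES = {
    "no": 0,
    "sometimes": 1,
    "regularly": 2,
    "often": 2,
    "very_often": 2,
}

#: Default item-index → scale map (items numbered 1..50).  The instrument's
#: published assignment is keyed by item text; this structural default keeps
#: the 16/12/5/16 composition (one item of the 50 remains unassigned) and can
#: be overridden via the ``item_map`` argument of :func:`score_4dsq`.
DEFAULT_ITEM_MAP: dict[int, str] = {
    **{i: "somatisation" for i in range(1, 17)},
    **{i: "stress" for i in range(17, 33)},
    **{i: "anxiety" for i in range(33, 45)},
    **{i: "depression" for i in range(45, 50)},
}

#: Clinical cut-offs ("moderately elevated" lower bounds) are carried only as
#: optional configuration; they play no role in the analysis pipeline.
CLINICAL_CUTOFFS_MODERATE = {"stress": 11, "anxiety": 4, "depression": 3, "somatisation": 11}

DEFAULT_FLOOR_THRESHOLD = 0.8


class UnknownCategoryError(ValueError):
    pass


@dataclass(frozen=True)
class FourDSQScores:
    """Scale sums at one questionnaire date; None marks an unscorable scale."""

    participant_id: str
    date: Date
    stress: int | None
    anxiety: int | None
    depression: int | None
    somatisation: int | None

    def as_dict(self) -> dict[str, int | None]:
        return {s: getattr(self, s) for s in SCALES}


@dataclass(frozen=True)
class ChangeScores:
    """Score differences between two consecutive questionnaires."""

    participant_id: str
    start_date: Date
    end_date: Date
    stress_increase: int | None
    anxiety_increase: int | None
    depression_increase: int | None
    somatisation_increase: int | None

    def as_dict(self) -> dict[str, int | None]:
        return {f"{s}_increase": getattr(self, f"{s}_increase") for s in SCALES}


@dataclass(frozen=True)
class FloorReport:
    scale: str
    zero_fraction: float
    flagged: bool


def recode_item(response: str) -> int:
    """Recode one response category to its 0/1/2 item score."""
    try:
        return CATEGORY_SCORES[response]
    except KeyError:
        raise UnknownCategoryError(f"unknown response category: {response!r}") from None


def validate_item_map(item_map: Mapping[int, str]) -> None:
    counts = {s: 0 for s in SCALES}
    for idx, scale in item_map.items():
        if not 1 <= idx <= 50:
            raise ValueError(f"item index {idx} outside 1..50")
        if scale not in SCALES:
            raise ValueError(f"unknown scale {scale!r} for item {idx}")
        counts[scale] += 1
    if counts != SCALE_ITEM_COUNTS:
        raise ValueError(f"scale composition {counts} != required {SCALE_ITEM_COUNTS}")


def score_4dsq(
    participant_id: str,
    date: Date,
    items: Mapping[int, str | None],
    item_map: Mapping[int, str] = DEFAULT_ITEM_MAP,
) -> FourDSQScores:
    """Sum recoded item responses into the four scale scores.

    ``items`` maps item index (1..50) to a response category or None.  A
    scale with any missing item yields a missing (None) score — no
    pro-rating — and logs a warning.
    """
    validate_item_map(item_map)
    sums: dict[str, int | None] = {s: 0 for s in SCALES}
    for idx, scale in item_map.items():
        response = items.get(idx)
        if response is None:
            if sums[scale] is not None:
                logger.warning(
                    "participant %s %s: missing item %d, scale %s unscorable",
                    participant_id, date, idx, scale,
                )
            sums[scale] = None
        elif sums[scale] is not None:
            sums[scale] += recode_item(response)
    return FourDSQScores(participant_id, date, **sums)


def score_table(responses, item_map: Mapping[int, str] = DEFAULT_ITEM_MAP) -> dict[str, list[FourDSQScores]]:
    """Score a wide response table (participant_id, date, item_1..item_50).

    Empty strings / NaN are treated as missing responses.  Returns scored
    questionnaires grouped by participant, sorted by date.
    """
    import pandas as pd

    out: dict[str, list[FourDSQScores]] = {}
    for _, row in responses.iterrows():
        items: dict[int, str | None] = {}
        for i in range(1, 51):
            v = row.get(f"item_{i}")
            items[i] = None if v is None or (isinstance(v, float) and np.isnan(v)) or v == "" else str(v)
        scored = score_4dsq(
            str(row["participant_id"]), pd.Timestamp(row["date"]).date(), items, item_map
        )
        out.setdefault(scored.participant_id, []).append(scored)
    for pid in out:
        out[pid].sort(key=lambda s: s.date)
    return out


def scores_frame(scored: dict[str, list[FourDSQScores]]):
    """Flatten scored questionnaires into the ``fdsq_scores.csv`` schema."""
    import pandas as pd

    rows = []
    for pid in sorted(scored):
        for s in scored[pid]:
            rows.append({"participant_id": pid, "date": s.date.isoformat(), **s.as_dict()})
    return pd.DataFrame(rows)


def change_scores(earlier: FourDSQScores, later: FourDSQScores) -> ChangeScores:
    """Later minus earlier, per scale; positive means an increase."""
    if earlier.participant_id != later.participant_id:
        raise ValueError("change scores require the same participant")
    if not later.date > earlier.date:
        raise ValueError("later questionnaire must postdate the earlier one")
    deltas = {}
    for s in SCALES:
        a, b = getattr(earlier, s), getattr(later, s)
        deltas[f"{s}_increase"] = None if a is None or b is None else b - a
    return ChangeScores(earlier.participant_id, earlier.date, later.date, **deltas)


def floor_effect_check(
    scores: Sequence[int],
    scale: str = "",
    zero_fraction_threshold: float = DEFAULT_FLOOR_THRESHOLD,
) -> FloorReport:
    """Screen one scale's scores for a floor effect.

    Flags when the proportion of zero scores reaches the threshold; a flagged
    scale carries too little variance for association modelling and the
    regression layer refuses it unless explicitly forced.
    """
    values = [s for s in scores if s is not None]
    if not values:
        raise ValueError("at least one score required")
    zero_fraction = float(np.mean([v == 0 for v in values]))
    return FloorReport(scale, zero_fraction, zero_fraction >= zero_fraction_threshold)
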