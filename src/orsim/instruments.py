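"""Rating instruments: the Global Rating Scale and Crisis Management Checklist.

The GRS is a five-item, seven-point Likert instrument (overall performance,
state-change detection, situational awareness, therapy/resource utilization,
and the subject's perceived crisis resolution).  The CMC is an eleven-item
checklist in three subscales; positive items are scored trichotomously
yes=2 / marginal=1 / no=0, and three penalty items ("missed detection",
"one or more incorrect diagnoses", "one or more inappropriate actions") are
scored with negative points — by default the mirrored scale 0 / −1 / −2,
configurable because published forms differ on the magnitudes.

Rating data travel as a long-format table with one row per
(rater, subject, scenario, instrument, item).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .errors import DomainError, MissingDataError, ValidationError

__all__ = [
    "GRS_ITEMS",
    "CMC_SUBSCALES",
    "CMC_ITEMS",
    "CMC_NEGATIVE_ITEMS",
    "CMC_LOW_DISCRIMINATION_ITEMS",
    "GRSRating",
    "CMCRating",
    "score_grs",
    "score_cmc",
    "items_for",
    "validate_rating_table",
    "rating_totals",
    "aggregate_scores",
]

GRS_ITEMS: Tuple[str, ...] = (
    "overall_performance",
    "state_change_detection",
    "situational_awareness",
    "therapy_resource_utilization",
    "perceived_crisis_resolution",
)

#: Subscale -> ordered item names.  Penalty items carry negative scores.
CMC_SUBSCALES: Dict[str, Tuple[str, ...]] = {
    "state_change_detection": (
        "timely_prompt_detection",
        "complete_detection",
        "missed_detection",
    ),
    "situational_awareness": (
        "complete_correct_differential",
        "prioritized_differential_list",
        "reassesses_situation",
        "incorrect_diagnoses",
    ),
    "therapy_resource_utilization": (
        "timely_therapy",
        "prioritized_actions",
        "appropriate_therapy_action",
        "inappropriate_actions",
    ),
}

CMC_ITEMS: Tuple[str, ...] = tuple(i for items in CMC_SUBSCALES.values() for i in items)

CMC_NEGATIVE_ITEMS = frozenset({"missed_detection", "incorrect_diagnoses", "inappropriate_actions"})

#: Items flagged for removal after the first validation round (one per
#: subscale, all penalty items).
CMC_LOW_DISCRIMINATION_ITEMS: Tuple[str, ...] = (
    "missed_detection",
    "incorrect_diagnoses",
    "inappropriate_actions",
)

_POSITIVE_SCALE = (0, 1, 2)
_NEGATIVE_SCALE = (0, -1, -2)


@dataclass(frozen=True)
class GRSRating:
    """One rater's five GRS item scores (each 1..7)."""

    overall_performance: int
    state_change_detection: int
    situational_awareness: int
    therapy_resource_utilization: int
    perceived_crisis_resolution: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not 1 <= int(v) <= 7:
                raise ValidationError(f"GRS item {f.name!r} must be in 1..7, got {v}")

    def as_dict(self) -> Dict[str, int]:
        return {f.name: int(getattr(self, f.name)) for f in fields(self)}


@dataclass(frozen=True)
class CMCRating:
    """One rater's eleven CMC item scores (already signed).

    Positive items take values in {0, 1, 2}; penalty items in the configured
    negative scale (default {0, −1, −2}).
    """

    scores: Mapping[str, int]
    negative_scale: Tuple[int, int, int] = _NEGATIVE_SCALE

    def __post_init__(self) -> None:
        unknown = set(self.scores) - set(CMC_ITEMS)
        if unknown:
            raise ValidationError(f"unknown CMC items: {sorted(unknown)}")
        missing = set(CMC_ITEMS) - set(self.scores)
        if missing:
            raise ValidationError(f"missing CMC items: {sorted(missing)}")
        for item, v in self.scores.items():
            allowed = self.negative_scale if item in CMC_NEGATIVE_ITEMS else _POSITIVE_SCALE
            if v not in allowed:
                raise ValidationError(
                    f"CMC item {item!r} must be in {sorted(allowed)}, got {v}"
                )

    def as_dict(self) -> Dict[str, int]:
        return dict(self.scores)


def score_grs(rating: GRSRating, include_items: Optional[Iterable[str]] = None) -> int:
    """Total GRS score: sum over the included items (default all five).

    Excluding ``perceived_crisis_resolution`` gives the item-removal variant
    reported alongside the full total.
    """
    scores = rating.as_dict()
    items = tuple(include_items) if include_items is not None else GRS_ITEMS
    unknown = set(items) - set(GRS_ITEMS)
    if unknown:
        raise ValidationError(f"unknown GRS items: {sorted(unknown)}")
    return sum(scores[i] for i in items)


def score_cmc(
    rating: CMCRating, include_items: Optional[Iterable[str]] = None
) -> Dict[str, int]:
    """Subscale totals and grand total for one CMC rating.

    ``include_items`` restricts scoring (e.g. dropping the three
    low-discrimination penalty items); by default all eleven count.
    """
    scores = rating.as_dict()
    items = set(include_items) if include_items is not None else set(CMC_ITEMS)
    unknown = items - set(CMC_ITEMS)
    if unknown:
        raise ValidationError(f"unknown CMC items: {sorted(unknown)}")
    result: Dict[str, int] = {}
    total = 0
    for subscale, sub_items in CMC_SUBSCALES.items():
        s = sum(scores[i] for i in sub_items if i in items)
        result[subscale] = s
        total += s
    result["total"] = total
    return result


# ---------------------------------------------------------------------------
# Long-format rating tables
# ---------------------------------------------------------------------------

RATING_COLUMNS = ["rater_id", "subject_id", "scenario", "instrument", "item", "score"]


def items_for(instrument: str) -> Tuple[str, ...]:
    if instrument == "grs":
        return GRS_ITEMS
    if instrument == "cmc":
        return CMC_ITEMS
    raise DomainError(f"unknown instrument {instrument!r} (expected 'grs' or 'cmc')")


def validate_rating_table(table: pd.DataFrame, require_complete: bool = True) -> pd.DataFrame:
    """Check schema, key uniqueness, item vocabulary, and design completeness.

    A complete design has every (rater, subject, scenario) cell carrying all
    of its instrument's items.  Returns the validated table.
    """
    missing_cols = [c for c in RATING_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"rating table missing columns: {missing_cols}")
    key = ["rater_id", "subject_id", "scenario", "instrument", "item"]
    dupes = table.duplicated(subset=key)
    if dupes.any():
        raise ValidationError(
            f"duplicate rating keys, first at row {int(dupes.idxmax())}"
        )
    for instrument, group in table.groupby("instrument"):
        valid = set(items_for(str(instrument)))
        bad = set(group["item"]) - valid
        if bad:
            raise ValidationError(f"{instrument}: unknown items {sorted(bad)}")
        if require_complete:
            counts = group.groupby(["rater_id", "subject_id", "scenario"])["item"].nunique()
            incomplete = counts[counts != len(valid)]
            if len(incomplete):
                raise MissingDataError(
                    f"{instrument}: incomplete cells (expected {len(valid)} items): "
                    f"{incomplete.index.tolist()[:5]}"
                )
    return table


def rating_totals(
    table: pd.DataFrame,
    instrument: str,
    include_items: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Instrument totals per (rater, subject, scenario), long table in →
    wide totals out."""
    items = set(include_items) if include_items is not None else set(items_for(instrument))
    sub = table[(table["instrument"] == instrument) & (table["item"].isin(items))]
    if sub.empty:
        raise DomainError(f"no ratings for instrument {instrument!r}")
    return (
        sub.groupby(["rater_id", "subject_id", "scenario"])["score"]
        .sum()
        .rename("total")
        .reset_index()
    )


def aggregate_scores(
    table: pd.DataFrame,
    by: str,
    instrument: str,
    include_items: Optional[Iterable[str]] = None,
) -> pd.Series:
    """Mean instrument totals grouped by ``subject``, ``scenario`` or ``rater``.

    Totals are computed per (rater, subject, scenario) first, then averaged
    across the remaining design factors — for ``by="subject"`` this is the
    per-subject mean of rater-averaged totals over all scenarios.
    """
    group_col = {"subject": "subject_id", "scenario": "scenario", "rater": "rater_id"}.get(by)
    if group_col is None:
        raise DomainError(f"by must be subject|scenario|rater, got {by!r}")
    totals = rating_totals(table, instrument, include_items)
    if totals.empty:
        raise DomainError("empty rating group")
    return totals.groupby(group_col)["total"].mean()
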