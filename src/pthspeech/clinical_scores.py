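"""SCAT-5 Symptom Evaluation and Beck Depression Inventory (BDI) scoring.

SCAT-5 Symptom Evaluation: 22 items rated 0 (none) to 6 (severe); scored as
the number of endorsed symptoms (0-22) and total symptom severity (0-132).
BDI: 21 items scored 0-3, summed to a total (0-63) banded as none (0-13),
mild (14-19), moderate (20-28), severe (29-63).

RAVLT delayed recall enters the cohort data only as a supplied z-score
covariate; it is not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

from .errors import ValidationError

SCAT5_ITEMS = 22
SCAT5_MAX_RATING = 6
BDI_ITEMS = 21
BDI_MAX_SCORE = 3

BDI_BANDS = (
    (0, 13, "none"),
    (14, 19, "mild"),
    (20, 28, "moderate"),
    (29, 63, "severe"),
)


def _validate(values: Sequence[int], n_items: int, max_value: int, name: str) -> Tuple[int, ...]:
    items = tuple(values)
    if len(items) != n_items:
        raise ValidationError(f"{name} requires exactly {n_items} items, got {len(items)}")
    for v in items:
        if not isinstance(v, (int,)) or isinstance(v, bool) or not (0 <= v <= max_value):
            raise ValidationError(f"{name} item {v!r} outside 0..{max_value}")
    return items


@dataclass(frozen=True)
class Scat5Response:
    item_ratings: Tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "item_ratings",
            _validate(self.item_ratings, SCAT5_ITEMS, SCAT5_MAX_RATING, "SCAT-5"),
        )


@dataclass(frozen=True)
class BdiResponse:
    item_scores: Tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "item_scores",
            _validate(self.item_scores, BDI_ITEMS, BDI_MAX_SCORE, "BDI"),
        )


def score_scat5(r: Scat5Response) -> Tuple[int, int]:
    """(symptom_count, symptom_severity): endorsed items and summed ratings."""
    count = sum(1 for v in r.item_ratings if v > 0)
    severity = sum(r.item_ratings)
    return count, severity


def score_bdi(r: BdiResponse) -> Tuple[int, str]:
    """(total, category) with the standard BDI severity bands."""
    total = sum(r.item_scores)
    for lo, hi, label in BDI_BANDS:
        if lo <= total <= hi:
            return total, label
    raise AssertionError("unreachable: bands partition 0..63")
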