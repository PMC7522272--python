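"""Combined neurological/behavioral assessment (NBA) rubric and scoring.

Eleven items: five neurological-assessment items (max sub-total 9) and six
wellness items (max sub-total 10).  A living animal scores 0-19; death is
scored 20 regardless of item values.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .errors import ValidationError

__all__ = [
    "NBARecord",
    "ITEM_MAX",
    "DEATH_SCORE",
    "MAX_ALIVE_SCORE",
    "score_nba",
    "validate_nba",
    "nba_items_from_total",
    "aggregate_daily",
]

#: per-item maximum scores, in rubric order
ITEM_MAX: dict[str, int] = {
    "neck_twist": 1,
    "righting_reflex": 2,
    "forepaws_extension": 2,
    "hind_limbs_extension": 2,
    "postural_reflex": 2,
    "facial_grimace": 2,
    "ears": 2,
    "exploration": 2,
    "eating": 1,
    "drinking": 1,
    "grooming": 2,
}

DEATH_SCORE = 20
MAX_ALIVE_SCORE = sum(ITEM_MAX.values())  # 19


@dataclass(frozen=True)
class NBARecord:
    """Item-level NBA scores for one observation session."""

    neck_twist: int = 0
    righting_reflex: int = 0
    forepaws_extension: int = 0
    hind_limbs_extension: int = 0
    postural_reflex: int = 0
    facial_grimace: int = 0
    ears: int = 0
    exploration: int = 0
    eating: int = 0
    drinking: int = 0
    grooming: int = 0
    is_dead: bool = False

    def items(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in ITEM_MAX}


def validate_nba(record: NBARecord) -> list[str]:
    """Return one violation message per out-of-range item (empty iff valid)."""
    violations = []
    for name, maximum in ITEM_MAX.items():
        value = getattr(record, name)
        if not isinstance(value, (int,)) or isinstance(value, bool):
            violations.append(f"{name} must be an integer in [0, {maximum}]")
        elif not 0 <= value <= maximum:
            violations.append(f"{name} must lie in [0, {maximum}], got {value}")
    return violations


def score_nba(record: NBARecord) -> int:
    """Total NBA score: sum of the 11 items, or 20 for a dead animal."""
    violations = validate_nba(record)
    if violations:
        raise ValidationError("; ".join(violations))
    if record.is_dead:
        return DEATH_SCORE
    return sum(record.items().values())


def nba_items_from_total(total: int) -> NBARecord:
    """Deterministically decompose a total into a valid item-level record.

    Items are filled greedily in rubric order; a total of 20 maps to death.
    Inverse of :func:`score_nba` in the sense ``score_nba(result) == total``.
    """
    if not 0 <= total <= DEATH_SCORE:
        raise ValidationError(f"total must lie in [0, {DEATH_SCORE}], got {total}")
    if total == DEATH_SCORE:
        return NBARecord(is_dead=True)
    values = {}
    remaining = total
    for name, maximum in ITEM_MAX.items():
        take = min(remaining, maximum)
        values[name] = take
        remaining -= take
    return NBARecord(**values)


def aggregate_daily(session_totals: Sequence[int]) -> int:
    """Daily NBA value from repeated sessions: mean, rounded half-up.

    Death (20) in any session dominates the day.
    """
    if len(session_totals) == 0:
        raise ValidationError("no session totals to aggregate")
    if any(t == DEATH_SCORE for t in session_totals):
        return DEATH_SCORE
    mean = Decimal(sum(session_totals)) / Decimal(len(session_totals))
    return int(mean.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
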