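"""Simulator Sickness Questionnaire (SSQ) scoring.

Sixteen symptom items, each rated 0-3, are summed into three non-mutually
exclusive factors — nausea (N), oculomotor (O), disorientation (D) — and
weighted: N x 9.54, O x 7.58, D x 13.92, total = (N + O + D) x 3.74.
Several items belong to more than one factor (e.g. general discomfort counts
toward both N and O).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "SSQ_ITEMS",
    "ITEM_FACTORS",
    "N_WEIGHT",
    "O_WEIGHT",
    "D_WEIGHT",
    "TOTAL_WEIGHT",
    "SSQResponse",
    "SSQScores",
    "score_ssq",
]

N_WEIGHT = 9.54
O_WEIGHT = 7.58
D_WEIGHT = 13.92
TOTAL_WEIGHT = 3.74

#: The canonical 16 SSQ items, in administration order.
SSQ_ITEMS = (
    "general discomfort",
    "fatigue",
    "headache",
    "eyestrain",
    "difficulty focusing",
    "increased salivation",
    "sweating",
    "nausea",
    "difficulty concentrating",
    "fullness of head",
    "blurred vision",
    "dizziness (eyes open)",
    "dizziness (eyes closed)",
    "vertigo",
    "stomach awareness",
    "burping",
)

# item -> factor membership, exposed read-only for audit; each factor sums
# 7 items, with overlaps across factors
_ITEM_FACTORS = {
    "general discomfort": ("N", "O"),
    "fatigue": ("O",),
    "headache": ("O",),
    "eyestrain": ("O",),
    "difficulty focusing": ("O", "D"),
    "increased salivation": ("N",),
    "sweating": ("N",),
    "nausea": ("N", "D"),
    "difficulty concentrating": ("N", "O"),
    "fullness of head": ("D",),
    "blurred vision": ("O", "D"),
    "dizziness (eyes open)": ("D",),
    "dizziness (eyes closed)": ("D",),
    "vertigo": ("D",),
    "stomach awareness": ("N",),
    "burping": ("N",),
}
ITEM_FACTORS: Mapping[str, tuple[str, ...]] = MappingProxyType(_ITEM_FACTORS)

_VALID_RATINGS = {0, 1, 2, 3}


@dataclass(frozen=True)
class SSQResponse:
    """One administration: 16 item ratings, each in {0, 1, 2, 3}."""

    ratings: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(SSQ_ITEMS) - set(self.ratings)
        if missing:
            raise ValueError(f"missing SSQ items: {sorted(missing)}")
        extra = set(self.ratings) - set(SSQ_ITEMS)
        if extra:
            raise ValueError(f"unknown SSQ items: {sorted(extra)}")
        for item, rating in self.ratings.items():
            if rating not in _VALID_RATINGS:
                raise ValueError(f"rating for {item!r} must be in 0..3, got {rating!r}")
        object.__setattr__(self, "ratings", MappingProxyType(dict(self.ratings)))


@dataclass(frozen=True)
class SSQScores:
    """Raw factor sums and the weighted subscale / total scores."""

    n_raw: int
    o_raw: int
    d_raw: int
    n_score: float
    o_score: float
    d_score: float
    total: float


def score_ssq(resp: SSQResponse) -> SSQScores:
    """Score a 16-item SSQ response into N/O/D subscale and total scores."""
    sums = {"N": 0, "O": 0, "D": 0}
    for item, factors in ITEM_FACTORS.items():
        rating = resp.ratings[item]
        for factor in factors:
            sums[factor] += rating
    n_raw, o_raw, d_raw = sums["N"], sums["O"], sums["D"]
    return SSQScores(
        n_raw=n_raw,
        o_raw=o_raw,
        d_raw=d_raw,
        n_score=N_WEIGHT * n_raw,
        o_score=O_WEIGHT * o_raw,
        d_score=D_WEIGHT * d_raw,
        total=TOTAL_WEIGHT * (n_raw + o_raw + d_raw),
    )
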