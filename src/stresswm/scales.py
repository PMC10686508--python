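"""Life-events and Likert questionnaire definitions.

Two weighted life-events checklists index cumulative stress: the Life
Events Scale for Students (LESS, 36 items, total 0-1849 life-change units)
for young adults and the Social Readjustment Rating Scale (SRRS, 43 items,
total 0-1466) for older adults.  The published analyses only use the
weighted totals and their medians, so the default per-item weight tables
here are synthetic: deterministic descending weights constructed to sum to
the printed scale maxima.  Substitute real item weights via
``ScaleDef(name, items=...)`` when they are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["ScaleDef", "LESS", "SRRS", "LikertScaleDef", "PSS10", "STAI_S", "STAI_T"]


@dataclass(frozen=True)
class ScaleDef:
    """A weighted binary-endorsement life-events checklist."""

    name: str
    items: tuple  # of (item_id, weight in life-change units)

    def __post_init__(self) -> None:
        if len({item_id for item_id, _ in self.items}) != len(self.items):
            raise ValueError("duplicate item ids")
        if any(weight <= 0 for _, weight in self.items):
            raise ValueError("weights must be positive")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def weights(self) -> tuple:
        return tuple(weight for _, weight in self.items)

    @property
    def max_score(self) -> int:
        return sum(self.weights)


def _synthetic_weights(n_items: int, total: int) -> tuple:
    """Deterministic descending integer weights summing exactly to total.

    A linear ramp from roughly 1.5x down to 0.5x the mean weight, with the
    rounding remainder folded into the heaviest item.  Synthetic: stands in
    for the instruments' real life-change units, which are not reproduced
    here; only the total and its distribution matter downstream.
    """
    mean = total / n_items
    raw = [mean * (1.5 - i / (n_items - 1)) for i in range(n_items)]
    weights = [max(1, round(w)) for w in raw]
    weights[0] += total - sum(weights)
    if weights[0] < weights[1]:
        raise AssertionError("remainder folding broke monotonicity")
    return tuple(weights)


def _make_scale(name: str, n_items: int, total: int) -> ScaleDef:
    weights = _synthetic_weights(n_items, total)
    items = tuple((f"{name.lower()}_{i + 1:02d}", w) for i, w in enumerate(weights))
    return ScaleDef(name=name, items=items)


LESS = _make_scale("LESS", 36, 1849)
SRRS = _make_scale("SRRS", 43, 1466)


@dataclass(frozen=True)
class LikertScaleDef:
    """A fixed-length Likert questionnaire with reverse-scored items."""

    name: str
    n_items: int
    min_rating: int
    max_rating: int
    reverse_items: frozenset  # 1-based item indices

    def __post_init__(self) -> None:
        if self.min_rating >= self.max_rating:
            raise ValueError("min_rating must be below max_rating")
        if any(not 1 <= i <= self.n_items for i in self.reverse_items):
            raise ValueError("reverse item index out of range")

    @property
    def score_range(self) -> tuple:
        return (self.n_items * self.min_rating, self.n_items * self.max_rating)

    def score(self, responses: Sequence[int]) -> int:
        """Total score with reverse items mapped ``max + min - x`` first."""
        if len(responses) != self.n_items:
            raise ValueError(f"{self.name} expects {self.n_items} responses")
        total = 0
        for index, value in enumerate(responses, start=1):
            if not self.min_rating <= value <= self.max_rating:
                raise ValueError(
                    f"response {value} outside [{self.min_rating}, {self.max_rating}]"
                )
            if index in self.reverse_items:
                value = self.max_rating + self.min_rating - value
            total += value
        return total


# PSS-10: 0-4 ratings; the four positively-phrased coping items (4, 5, 7, 8)
# are reverse-scored, the six distress items are not.  Range 0-40.
PSS10 = LikertScaleDef(
    name="PSS-10", n_items=10, min_rating=0, max_rating=4,
    reverse_items=frozenset({4, 5, 7, 8}),
)

# Spielberger state/trait anxiety: 20 items rated 1-4, range 20-80.  The
# reverse-keyed (anxiety-absent) items per the standard Y form.
STAI_S = LikertScaleDef(
    name="STAI-S", n_items=20, min_rating=1, max_rating=4,
    reverse_items=frozenset({1, 2, 5, 8, 10, 11, 15, 16, 19, 20}),
)
STAI_T = LikertScaleDef(
    name="STAI-T", n_items=20, min_rating=1, max_rating=4,
    reverse_items=frozenset({1, 3, 6, 7, 10, 13, 14, 16, 19}),
)
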