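"""Study-level effect estimates feeding the Bayesian meta-analysis.

Every contrast is summarised as a mean difference with its standard error,
the exchange format between scored participant data and the posterior
chain.  Sign conventions: age = young - older, stress = low - high, and the
age-by-stress interaction = (low - high among young) - (low - high among
older), so impaired high-stress older adults produce a negative interaction
on accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EffectEstimate",
    "group_contrast",
    "interaction_contrast",
    "speed_accuracy_check",
    "harmonic_mean",
]

CONTRASTS = ("age", "stress", "interaction", "stress_within_young", "stress_within_older")
OUTCOMES = ("percent_correct", "dprime", "rt_ms")

#: Cell keys of the 2x2 design, in (age_group, stress_group) order.
CELLS = (("young", "low"), ("young", "high"), ("older", "low"), ("older", "high"))


@dataclass(frozen=True)
class EffectEstimate:
    """One study's group contrast on one outcome."""

    study_label: str
    contrast: str
    outcome: str
    mean_diff: float
    sem: float
    n_total: int
    cell_ns: tuple = ()

    def __post_init__(self) -> None:
        if not self.sem > 0:
            raise ValueError("sem must be positive")
        if self.cell_ns and sum(self.cell_ns) != self.n_total:
            raise ValueError("n_total must equal the sum of cell_ns")


def harmonic_mean(values) -> float:
    """Harmonic mean of strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    if np.any(arr <= 0):
        raise ValueError("harmonic mean requires strictly positive values")
    return arr.size / np.sum(1.0 / arr)


def group_contrast(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    study_label: str = "",
    contrast: str = "age",
    outcome: str = "percent_correct",
) -> EffectEstimate:
    """Mean difference A - B with the unpooled (Welch) standard error.

    ``sem = sqrt(var(A)/n_A + var(B)/n_B)`` with sample (ddof=1) variances.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 scores")
    diff = a.mean() - b.mean()
    sem = math.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    return EffectEstimate(
        study_label=study_label,
        contrast=contrast,
        outcome=outcome,
        mean_diff=float(diff),
        sem=float(sem),
        n_total=int(a.size + b.size),
        cell_ns=(int(a.size), int(b.size)),
    )


def interaction_contrast(
    cells: Mapping[tuple, Sequence[float]],
    variant: str = "harmonic_scores",
    study_label: str = "",
    outcome: str = "percent_correct",
) -> EffectEstimate:
    """Age-by-stress interaction from the four design cells.

    The contrast is ``(low - high)_young - (low - high)_older`` on a cell
    summary.  With uneven cells the unweighted-means construction is used:

    - ``harmonic_scores`` (default): cell summary = harmonic mean of the
      cell's scores; requires strictly positive scores.
    - ``harmonic_ns``: cell summary = arithmetic mean; only the SE uses the
      harmonic cell size.
    - ``arithmetic``: plain cell means with the Welch-style SE
      ``sqrt(sum var_i / n_i)``.

    For the two harmonic variants the SE is ``sqrt(sum var_i / n_h)`` with
    ``n_h`` the harmonic mean of the four cell sizes.
    """
    if variant not in ("harmonic_scores", "harmonic_ns", "arithmetic"):
        raise ValueError(f"unknown variant {variant!r}")
    missing = [key for key in CELLS if key not in cells]
    if missing:
        raise ValueError(f"missing cells: {missing}")
    arrays = {key: np.asarray(cells[key], dtype=float) for key in CELLS}
    if any(arr.size < 2 for arr in arrays.values()):
        raise ValueError("each cell needs at least 2 scores")

    if variant == "harmonic_scores":
        summaries = {key: harmonic_mean(arr) for key, arr in arrays.items()}
    else:
        summaries = {key: float(arr.mean()) for key, arr in arrays.items()}
    diff = (
        summaries[("young", "low")]
        - summaries[("young", "high")]
        - (summaries[("older", "low")] - summaries[("older", "high")])
    )

    variances = {key: arr.var(ddof=1) for key, arr in arrays.items()}
    sizes = {key: arr.size for key, arr in arrays.items()}
    if variant == "arithmetic":
        var = sum(variances[key] / sizes[key] for key in CELLS)
    else:
        n_h = harmonic_mean(list(sizes.values()))
        var = sum(variances.values()) / n_h
    return EffectEstimate(
        study_label=study_label,
        contrast="interaction",
        outcome=outcome,
        mean_diff=float(diff),
        sem=math.sqrt(var),
        n_total=int(sum(sizes.values())),
        cell_ns=tuple(int(sizes[key]) for key in CELLS),
    )


@dataclass(frozen=True)
class SpeedAccuracyResult:
    r: float
    p_value: float
    tradeoff: bool


def speed_accuracy_check(
    percent_correct_hits: Sequence[float],
    mean_hit_rt: Sequence[float],
    alpha: float = 0.05,
) -> SpeedAccuracyResult:
    """Screen for a speed-accuracy trade-off.

    A trade-off (slower responding buying higher accuracy) shows up as a
    significantly positive Pearson correlation between hit accuracy and
    mean hit RT; when flagged, downstream conclusions should rest on the RT
    outcome only.
    """
    acc = np.asarray(percent_correct_hits, dtype=float)
    rt = np.asarray(mean_hit_rt, dtype=float)
    if acc.size != rt.size or acc.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    res = stats.pearsonr(acc, rt)
    r, p = float(res.statistic), float(res.pvalue)
    return SpeedAccuracyResult(r=r, p_value=p, tradeoff=bool(r > 0 and p < alpha))
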