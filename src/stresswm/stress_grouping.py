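"""Cumulative-stress scoring and high/low group construction.

Participants are dichotomised at the sample median of their weighted
life-events total — per study-and-age cohort by default, or at a single
pooled median per scale.  Scores falling exactly on the median go to the
low-stress group (the conservative allocation when the hypothesis predicts
high-stress impairment).  Because a median split turns a covariate into a
factor, the split is only trustworthy when stress group is uncorrelated
with age group; :func:`independence_check` screens for that and warns
rather than aborts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scales import LikertScaleDef, ScaleDef

__all__ = [
    "StressGroupAssignment",
    "life_events_score",
    "median_split",
    "split_participants",
    "independence_check",
    "likert_score",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StressGroupAssignment:
    participant_id: str
    life_events_score: float
    split_value: float
    split_mode: str
    group: str  # "low" or "high"


def life_events_score(endorsements: Sequence, scale: ScaleDef) -> int:
    """Weighted sum of binary item endorsements, in life-change units."""
    arr = np.asarray(endorsements)
    if arr.shape != (scale.n_items,):
        raise ValueError(f"{scale.name} expects {scale.n_items} endorsements")
    if not np.isin(arr, [0, 1, False, True]).all():
        raise ValueError("endorsements must be binary")
    return int(np.dot(arr.astype(int), scale.weights))


def median_split(scores: Sequence[float]) -> tuple[float, list]:
    """Split scores at the sample median; ties go to the low group.

    Returns ``(split_value, groups)`` with groups aligned to the input
    order.  The median is the midpoint convention (mean of the central
    pair for even n).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 scores to split")
    split = float(np.median(arr))
    groups = ["low" if score <= split else "high" for score in arr]
    return split, groups


def split_participants(
    participants: pd.DataFrame,
    mode: str = "per_study",
) -> pd.DataFrame:
    """Assign every participant to a high/low cumulative-stress group.

    Expects columns ``participant_id``, ``study_label``, ``age_group``,
    ``scale_name`` and ``life_events_score``.  ``per_study`` computes one
    median per study x age cohort (each cohort answered a single scale);
    ``pooled`` computes one median per scale across all studies.
    """
    if mode not in ("per_study", "pooled"):
        raise ValueError(f"unknown split mode {mode!r}")
    keys = ["scale_name"] if mode == "pooled" else ["study_label", "scale_name"]
    frames = []
    for _, cohort in participants.groupby(keys, sort=False):
        split, groups = median_split(cohort["life_events_score"].to_numpy())
        assigned = cohort[
            ["participant_id", "study_label", "age_group", "scale_name",
             "life_events_score"]
        ].copy()
        assigned["split_value"] = split
        assigned["split_mode"] = mode
        assigned["stress_group"] = groups
        frames.append(assigned)
    result = pd.concat(frames, ignore_index=True)
    counts = result["stress_group"].value_counts().to_dict()
    log.info("stress split (%s): %s", mode, counts)
    return result


@dataclass(frozen=True)
class IndependenceResult:
    correlation: float
    p_value: float
    table: tuple  # 2x2 counts ((low&young, low&older), (high&young, high&older))


def independence_check(
    age_groups: Sequence[str],
    stress_groups: Sequence[str],
    alpha: float = 0.05,
) -> IndependenceResult:
    """Phi correlation between the two binary design factors.

    The median split is a valid grouping device only while stress group is
    uncorrelated with age group; a significant association is reported with
    a warning so the analyst can decide, matching how the screen is used in
    practice (checked, then proceeded).
    """
    age = np.asarray(age_groups)
    stress = np.asarray(stress_groups)
    if age.shape != stress.shape or age.size < 2:
        raise ValueError("need two equal-length label vectors")
    x = (age == "older").astype(float)
    y = (stress == "high").astype(float)
    table = tuple(
        tuple(int(np.sum((y == sy) & (x == sx))) for sx in (0.0, 1.0))
        for sy in (0.0, 1.0)
    )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("both factors need two levels for an association test")
    res = stats.pearsonr(x, y)
    phi, p = float(res.statistic), float(res.pvalue)
    if p < alpha:
        warnings.warn(
            f"age and stress group are associated (phi={phi:.3f}, p={p:.4f}); "
            "the median split may confound the design",
            UserWarning,
            stacklevel=2,
        )
    return IndependenceResult(correlation=phi, p_value=p, table=table)


def likert_score(responses: Sequence[int], scale: LikertScaleDef) -> int:
    """Total questionnaire score with reverse-keyed items flipped first."""
    return scale.score(responses)
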