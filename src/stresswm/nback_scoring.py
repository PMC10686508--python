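"""Scoring of trial-level 2-back data.

A 2-back run is 120 trials in 3 blocks of 40 (13 targets, 27 non-targets
per block).  Responses partition into hits, misses, false alarms and
correct rejections; from these we compute

- percent correct over all 120 trials: (hits + correct rejections) / 120 x 100,
- per-block sensitivity d' = Phi^-1(H) - Phi^-1(F), with the standard
  1/(2n) edge corrections for perfect hit rates and zero false-alarm rates
  (n = number of target / non-target trials respectively),
- mean hit reaction time after a single-pass 2.5-SD trim per
  participant-block.

Blocks with non-positive d' signal response confusion or bias and are
dropped from the d' aggregate; a participant whose every block fails is
flagged excluded.  Percent correct is always computed over all 120 trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlockScore",
    "classify_trials",
    "percent_correct",
    "corrected_rates",
    "dprime",
    "filter_blocks",
    "trim_rts",
    "score_blocks",
    "score_participants",
]

log = logging.getLogger(__name__)

TRIM_SD = 2.5


@dataclass(frozen=True)
class BlockScore:
    participant_id: str
    block: int
    hits: int
    misses: int
    correct_rejections: int
    false_alarms: int
    hit_rate: float
    fa_rate: float
    dprime: float
    mean_rt_ms: float  # trimmed, hits only; NaN when no hit RTs
    sd_rt_ms: float
    n_rt_trimmed_out: int


def classify_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Confusion counts per block for one participant's trials.

    Requires boolean ``is_target`` and ``responded`` columns; a response to
    a target is a hit, to a non-target a false alarm.
    """
    required = {"block", "is_target", "responded"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trials need columns {sorted(required)}")
    target = trials["is_target"].astype(bool)
    responded = trials["responded"].astype(bool)
    counts = pd.DataFrame(
        {
            "hits": (target & responded),
            "misses": (target & ~responded),
            "false_alarms": (~target & responded),
            "correct_rejections": (~target & ~responded),
        }
    )
    out = counts.groupby(trials["block"]).sum().astype(int)
    out.index.name = "block"
    return out


def percent_correct(hits: int, correct_rejections: int, n_trials: int) -> float:
    """(hits + correct rejections) / n_trials x 100."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if hits + correct_rejections > n_trials:
        raise ValueError("more correct trials than trials")
    return (hits + correct_rejections) / n_trials * 100.0


def corrected_rates(
    hits: int, misses: int, false_alarms: int, correct_rejections: int
) -> tuple[float, float]:
    """Hit and false-alarm rates with 1/(2n) edge corrections.

    A perfect hit rate becomes 1 - 1/(2 n_targets) and a zero false-alarm
    rate becomes 1/(2 n_nontargets), keeping both rates strictly interior
    so the normal quantiles in d' stay finite.  Zero hit rates and perfect
    false-alarm rates are corrected symmetrically.
    """
    if min(hits, misses, false_alarms, correct_rejections) < 0:
        raise ValueError("counts must be non-negative")
    n_targets = hits + misses
    n_nontargets = false_alarms + correct_rejections
    if n_targets == 0 or n_nontargets == 0:
        raise ValueError("block must contain both targets and non-targets")
    hit_rate = hits / n_targets
    if hit_rate == 1.0:
        hit_rate = 1.0 - 1.0 / (2 * n_targets)
    elif hit_rate == 0.0:
        hit_rate = 1.0 / (2 * n_targets)
    fa_rate = false_alarms / n_nontargets
    if fa_rate == 0.0:
        fa_rate = 1.0 / (2 * n_nontargets)
    elif fa_rate == 1.0:
        fa_rate = 1.0 - 1.0 / (2 * n_nontargets)
    return hit_rate, fa_rate


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Sensitivity d' = Phi^-1(H) - Phi^-1(F) for interior rates."""
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError("rates must be strictly between 0 and 1")
    return float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))


def filter_blocks(dprimes) -> np.ndarray:
    """Boolean mask of blocks retained for the d' aggregate (d' > 0)."""
    arr = np.asarray(dprimes, dtype=float)
    return arr > 0


def trim_rts(rts) -> np.ndarray:
    """Single-pass trim: keep RTs within 2.5 SD of their own mean.

    Mean and SD (population, matching the one-shot filter) are computed
    once over the input; the filter is not re-applied to the survivors.
    """
    arr = np.asarray(rts, dtype=float)
    if arr.size < 2:
        return np.ones(arr.size, dtype=bool)
    sd = arr.std()
    if sd == 0:
        return np.ones(arr.size, dtype=bool)
    return np.abs(arr - arr.mean()) <= TRIM_SD * sd


def score_blocks(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant-block confusion counts, rates, d' and trimmed RTs."""
    rows = []
    for (pid, block), chunk in trials.groupby(["participant_id", "block"], sort=True):
        target = chunk["is_target"].astype(bool).to_numpy()
        responded = chunk["responded"].astype(bool).to_numpy()
        hits = int((target & responded).sum())
        misses = int((target & ~responded).sum())
        fas = int((~target & responded).sum())
        crs = int((~target & ~responded).sum())
        hit_rate, fa_rate = corrected_rates(hits, misses, fas, crs)
        dp = dprime(hit_rate, fa_rate)
        hit_rts = chunk.loc[target & responded, "rt_ms"].to_numpy(dtype=float)
        hit_rts = hit_rts[~np.isnan(hit_rts)]
        keep = trim_rts(hit_rts)
        kept = hit_rts[keep]
        rows.append(
            BlockScore(
                participant_id=pid,
                block=int(block),
                hits=hits,
                misses=misses,
                correct_rejections=crs,
                false_alarms=fas,
                hit_rate=hit_rate,
                fa_rate=fa_rate,
                dprime=dp,
                mean_rt_ms=float(kept.mean()) if kept.size else float("nan"),
                sd_rt_ms=float(kept.std(ddof=1)) if kept.size > 1 else float("nan"),
                n_rt_trimmed_out=int(hit_rts.size - kept.size),
            )
        )
    return pd.DataFrame([vars(row) for row in rows])


def score_participants(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse block scores to one row per participant.

    ``percent_correct`` uses all trials; ``dprime_mean`` averages the
    retained (positive-d') blocks; ``mean_rt_ms`` pools the trimmed hit
    RTs of all blocks.  ``excluded_accuracy`` marks participants with no
    positive-d' block, whose ``dprime_mean`` is NaN.
    """
    blocks = score_blocks(trials)
    out = []
    rt_all = {
        pid: chunk for pid, chunk in trials.groupby("participant_id", sort=True)
    }
    for pid, chunk in blocks.groupby("participant_id", sort=True):
        n_trials = int(
            chunk[["hits", "misses", "false_alarms", "correct_rejections"]].to_numpy().sum()
        )
        pc = percent_correct(
            int(chunk["hits"].sum()), int(chunk["correct_rejections"].sum()), n_trials
        )
        retained = filter_blocks(chunk["dprime"].to_numpy())
        dp_mean = float(chunk["dprime"].to_numpy()[retained].mean()) if retained.any() else float("nan")
        # pool trimmed hit RTs across blocks
        part = rt_all[pid]
        target = part["is_target"].astype(bool) & part["responded"].astype(bool)
        kept_rts = []
        n_hit_rts = 0
        for _, block_chunk in part[target].groupby("block", sort=True):
            rts = block_chunk["rt_ms"].to_numpy(dtype=float)
            rts = rts[~np.isnan(rts)]
            n_hit_rts += rts.size
            kept_rts.append(rts[trim_rts(rts)])
        kept = np.concatenate(kept_rts) if kept_rts else np.array([])
        out.append(
            {
                "participant_id": pid,
                "percent_correct": pc,
                "dprime_mean": dp_mean,
                "blocks_retained": int(retained.sum()),
                "mean_rt_ms": float(kept.mean()) if kept.size else float("nan"),
                "rt_loss_fraction": (
                    (n_hit_rts - kept.size) / n_hit_rts if n_hit_rts else 0.0
                ),
                "excluded_accuracy": not retained.any(),
            }
        )
    scores = pd.DataFrame(out)
    n_excluded = int(scores["excluded_accuracy"].sum())
    if n_excluded:
        log.info(
            "%d participant(s) excluded from d' aggregation (no positive-d' block): %s",
            n_excluded,
            scores.loc[scores["excluded_accuracy"], "participant_id"].tolist(),
        )
    return scores
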