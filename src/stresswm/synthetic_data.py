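"""Simulation of multi-study 2-back / life-events datasets.

The generator emulates the design the analysis chain assumes: several
independent cross-sectional studies, each with a young (18-35) and an
older (60-85) adult cohort, every participant contributing a weighted
life-events questionnaire (LESS for young, SRRS for older) and 120 2-back
trials (3 blocks x 40 trials, 13 targets and 27 non-targets per block,
3000 ms response window).

Response model: an independent Bernoulli per trial (probability
``true_hit_prob`` on targets, ``true_fa_prob`` on non-targets — misses are
simply non-responses and carry no RT), with response times drawn from a
log-normal centred so that ``true_rt_location_ms`` is the mean, truncated
at the 3000 ms window.  Age, stress and age-by-stress effects shift the
per-cell accuracy (in percentage points, applied symmetrically to hit and
correct-rejection probabilities) and mean RT, with participant-level
heterogeneity on the logit / log scale so that between-subject spread is
realistic rather than purely binomial.

Stress group membership used for effect injection is the median split of
the realised life-events scores within each study-by-age cohort (ties to
low) — the same rule the analysis applies — so injected stress effects are
defined on the groups the downstream pipeline actually contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .scales import LESS, SRRS, ScaleDef

__all__ = [
    "SimConfig",
    "ParticipantMeta",
    "generate_sequence",
    "generate_responses",
    "generate_life_events",
    "generate_study",
    "export_csv",
    "DEFAULT_CELLS",
]

BLOCKS = 3
TRIALS_PER_BLOCK = 40
TARGETS_PER_BLOCK = 13
RESPONSE_WINDOW_MS = 3000.0
STIMULI = (1, 2, 3, 4)

#: Study cells mirroring the published sample sizes (an anchoring study of
#: 60 plus three replications of 40/58/58).
DEFAULT_CELLS = (
    ("Marshall", "young", 30),
    ("Marshall", "older", 30),
    ("Study 1", "young", 21),
    ("Study 1", "older", 19),
    ("Study 2A", "young", 31),
    ("Study 2A", "older", 27),
    ("Study 2B", "young", 29),
    ("Study 2B", "older", 29),
)

#: Life-events score location/spread per age group, centred on the pooled
#: medians (LESS 577, SRRS 786) with spreads matching the printed IQRs.
DEFAULT_STRESS_DISTRIBUTION = {
    "young": (577.0, 240.0),
    "older": (786.0, 170.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated multi-study dataset.

    Accuracy effects are in percentage points (positive = the reference
    group is better: young over older, low stress over high); RT effects
    are in milliseconds with the same young-minus-older / low-minus-high
    sign convention, so a negative age RT effect means young respond
    faster.  The interaction effect is added to the older/high-stress
    cell, matching the (low-high)_young - (low-high)_older contrast.

    Default effect sizes are the pooled posterior estimates of the
    replication series this package models (age 2.37 pp / -125 ms, stress
    2.88 pp, interaction 0 — the interaction evidence was inconclusive).
    """

    seed: int = 0
    cells: tuple = DEFAULT_CELLS
    baseline_hit_prob: float = 0.80
    baseline_fa_prob: float = 0.10
    rt_location_ms: float = 700.0
    rt_scale: float = 0.25
    age_effect_acc: float = 2.37
    stress_effect_acc: float = 2.88
    interaction_effect_acc: float = 0.0
    age_effect_rt: float = -125.0
    stress_effect_rt: float = 0.0
    interaction_effect_rt: float = 0.0
    stress_score_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_STRESS_DISTRIBUTION)
    )
    accuracy_heterogeneity_sd: float = 0.5  # logit scale
    rt_heterogeneity_sd: float = 0.15  # log scale

    def __post_init__(self) -> None:
        if not 0 < self.baseline_hit_prob < 1 or not 0 < self.baseline_fa_prob < 1:
            raise ValueError("baseline probabilities must lie in (0, 1)")
        if not 0 < self.rt_location_ms < RESPONSE_WINDOW_MS:
            raise ValueError("rt_location_ms must lie in (0, 3000)")
        if any(n < 2 for _, _, n in self.cells):
            raise ValueError("every cell needs n >= 2")
        if any(group not in ("young", "older") for _, group, _ in self.cells):
            raise ValueError("age_group must be 'young' or 'older'")


@dataclass(frozen=True)
class ParticipantMeta:
    participant_id: str
    study_label: str
    age_group: str
    age_years: int
    sex: str
    scale_name: str
    life_events_score: int
    true_hit_prob: float
    true_fa_prob: float
    true_rt_location_ms: float


def _batch_sequences(
    n_runs: int,
    trials_per_block: int,
    targets_per_block: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Stimuli and target flags for ``n_runs`` independent 40-trial blocks.

    A trial is a target iff its stimulus equals the stimulus two positions
    earlier in the same block, so the first two trials can never be
    targets; target positions are placed uniformly at random among the
    remaining ones, and non-target stimuli are drawn from the three digits
    that do not repeat the two-back stimulus.
    """
    eligible = trials_per_block - 2
    if targets_per_block < 0 or targets_per_block > eligible:
        raise ValueError(
            f"cannot place {targets_per_block} targets in {trials_per_block} trials"
        )
    is_target = np.zeros((n_runs, trials_per_block), dtype=bool)
    order = np.argsort(rng.random((n_runs, eligible)), axis=1)[:, :targets_per_block]
    rows = np.repeat(np.arange(n_runs), targets_per_block)
    is_target[rows, order.ravel() + 2] = True

    stim = np.zeros((n_runs, trials_per_block), dtype=np.int64)
    stim[:, :2] = rng.integers(1, 5, size=(n_runs, 2))
    for t in range(2, trials_per_block):
        two_back = stim[:, t - 2]
        r = rng.integers(1, 4, size=n_runs)  # rank among the 3 non-matching digits
        non_match = np.where(r < two_back, r, r + 1)
        stim[:, t] = np.where(is_target[:, t], two_back, non_match)
    return stim, is_target


def generate_sequence(
    block_count: int,
    trials_per_block: int,
    targets_per_block: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One participant's stimulus sequence with target flags."""
    stim, target = _batch_sequences(block_count, trials_per_block, targets_per_block, rng)
    return pd.DataFrame(
        {
            "block": np.repeat(np.arange(1, block_count + 1), trials_per_block),
            "trial_index": np.tile(np.arange(1, trials_per_block + 1), block_count),
            "stimulus": stim.ravel(),
            "is_target": target.ravel(),
        }
    )


def _truncated_lognormal(
    mean_ms: np.ndarray, log_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal samples with the given mean, truncated at the window."""
    mu = np.log(mean_ms) - 0.5 * log_sd**2
    z_max = (np.log(RESPONSE_WINDOW_MS) - mu) / log_sd
    u = rng.random(mean_ms.shape)
    z = norm.ppf(u * norm.cdf(z_max))
    return np.exp(mu + log_sd * z)


def generate_responses(
    sequence: pd.DataFrame,
    participant: ParticipantMeta,
    rng: np.random.Generator,
    rt_scale: float = 0.25,
) -> pd.DataFrame:
    """Bernoulli responses and truncated log-normal RTs for one run."""
    for prob in (participant.true_hit_prob, participant.true_fa_prob):
        if not 0 <= prob <= 1:
            raise ValueError("response probabilities must lie in [0, 1]")
    target = sequence["is_target"].to_numpy(dtype=bool)
    p = np.where(target, participant.true_hit_prob, participant.true_fa_prob)
    responded = rng.random(p.shape) < p
    rt = np.full(p.shape, np.nan)
    mean = np.full(int(responded.sum()), participant.true_rt_location_ms, dtype=float)
    rt[responded] = _truncated_lognormal(mean, rt_scale, rng)
    out = sequence.copy()
    out.insert(0, "participant_id", participant.participant_id)
    out["responded"] = responded
    out["rt_ms"] = rt
    return out


def generate_life_events(
    scale: ScaleDef,
    target_score_location: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary item endorsements whose weighted sum centres on the target.

    Every item is endorsed independently with probability
    ``target / max_score``, so the expected weighted total equals the
    target; the boundary targets 0 and max endorse nothing / everything.
    """
    if not 0 <= target_score_location <= scale.max_score:
        raise ValueError(
            f"target {target_score_location} outside [0, {scale.max_score}]"
        )
    p = target_score_location / scale.max_score
    return rng.random(scale.n_items) < p


def _tie_low_median_split(scores: np.ndarray) -> np.ndarray:
    """High-stress flags under the analysis's tie-to-low median rule."""
    return scores > np.median(scores)


def generate_study(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full multi-study dataset.

    Returns ``(participants, trials)`` data frames; deterministic for a
    fixed config (a single PCG64 stream consumed in a fixed order).
    """
    rng = np.random.default_rng(config.seed)
    participants: list[dict] = []
    trial_frames: list[pd.DataFrame] = []
    counter = 0

    for study_label in dict.fromkeys(label for label, _, _ in config.cells):
        study_rows: list[dict] = []
        for label, age_group, n in config.cells:
            if label != study_label:
                continue
            scale = LESS if age_group == "young" else SRRS
            loc, spread = config.stress_score_distribution[age_group]
            age_lo, age_hi = (18, 35) if age_group == "young" else (60, 85)
            latent = np.clip(
                rng.normal(loc, spread, size=n), 0.0, float(scale.max_score)
            )
            ages = rng.integers(age_lo, age_hi + 1, size=n)
            sexes = rng.choice(["f", "m"], size=n)
            scores = np.array(
                [
                    np.dot(
                        generate_life_events(scale, t, rng).astype(int), scale.weights
                    )
                    for t in latent
                ]
            )
            high = _tie_low_median_split(scores)
            acc_delta = np.zeros(n)
            rt_loc = np.full(n, config.rt_location_ms)
            if age_group == "older":
                acc_delta -= config.age_effect_acc / 100.0
                rt_loc -= config.age_effect_rt
            acc_delta -= np.where(high, config.stress_effect_acc / 100.0, 0.0)
            rt_loc -= np.where(high, config.stress_effect_rt, 0.0)
            if age_group == "older":
                acc_delta += np.where(
                    high, config.interaction_effect_acc / 100.0, 0.0
                )
                rt_loc += np.where(high, config.interaction_effect_rt, 0.0)

            hit_base = np.clip(config.baseline_hit_prob + acc_delta, 0.02, 0.98)
            fa_base = np.clip(config.baseline_fa_prob - acc_delta, 0.005, 0.95)
            jitter = rng.normal(0.0, config.accuracy_heterogeneity_sd, size=n)
            hit_p = expit(logit(hit_base) + jitter)
            fa_p = expit(logit(fa_base) - jitter)
            rt_jit = rng.normal(0.0, config.rt_heterogeneity_sd, size=n)
            rt_i = np.clip(
                rt_loc * np.exp(rt_jit - 0.5 * config.rt_heterogeneity_sd**2),
                100.0,
                0.95 * RESPONSE_WINDOW_MS,
            )

            for i in range(n):
                counter += 1
                study_rows.append(
                    {
                        "participant_id": f"p{counter:04d}",
                        "study_label": label,
                        "age_group": age_group,
                        "age_years": int(ages[i]),
                        "sex": str(sexes[i]),
                        "scale_name": scale.name,
                        "life_events_score": int(scores[i]),
                        "stress_group_true": "high" if high[i] else "low",
                        "true_hit_prob": float(hit_p[i]),
                        "true_fa_prob": float(fa_p[i]),
                        "true_rt_location_ms": float(rt_i[i]),
                    }
                )

        # trials for the whole study in one vectorised batch
        m = len(study_rows)
        stim, target = _batch_sequences(
            m * BLOCKS, TRIALS_PER_BLOCK, TARGETS_PER_BLOCK, rng
        )
        stim = stim.reshape(m, BLOCKS * TRIALS_PER_BLOCK)
        target = target.reshape(m, BLOCKS * TRIALS_PER_BLOCK)
        hit_p = np.array([row["true_hit_prob"] for row in study_rows])[:, None]
        fa_p = np.array([row["true_fa_prob"] for row in study_rows])[:, None]
        p = np.where(target, hit_p, fa_p)
        responded = rng.random(p.shape) < p
        rt = np.full(p.shape, np.nan)
        rt_loc = np.array([row["true_rt_location_ms"] for row in study_rows])
        mean = np.broadcast_to(rt_loc[:, None], p.shape)[responded]
        rt[responded] = _truncated_lognormal(mean.copy(), config.rt_scale, rng)

        pids = np.repeat(
            [row["participant_id"] for row in study_rows], BLOCKS * TRIALS_PER_BLOCK
        )
        trial_frames.append(
            pd.DataFrame(
                {
                    "participant_id": pids,
                    "study_label": study_label,
                    "block": np.tile(
                        np.repeat(np.arange(1, BLOCKS + 1), TRIALS_PER_BLOCK), m
                    ),
                    "trial_index": np.tile(
                        np.tile(np.arange(1, TRIALS_PER_BLOCK + 1), BLOCKS), m
                    ),
                    "stimulus": stim.ravel(),
                    "is_target": target.ravel(),
                    "responded": responded.ravel(),
                    "rt_ms": rt.ravel(),
                }
            )
        )
        participants.extend(study_rows)

    return pd.DataFrame(participants), pd.concat(trial_frames, ignore_index=True)


def export_csv(
    participants: pd.DataFrame, trials: pd.DataFrame, out_dir: Path
) -> tuple[Path, Path]:
    """Write ``participants.csv`` and ``trials.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p_path = out_dir / "participants.csv"
    t_path = out_dir / "trials.csv"
    participants.to_csv(p_path, index=False)
    trials.to_csv(t_path, index=False)
    return p_path, t_path


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A configuration with every group effect switched off."""
    base = SimConfig(
        seed=seed,
        age_effect_acc=0.0,
        stress_effect_acc=0.0,
        interaction_effect_acc=0.0,
        age_effect_rt=0.0,
        stress_effect_rt=0.0,
        interaction_effect_rt=0.0,
    )
    return replace(base, **overrides) if overrides else base
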