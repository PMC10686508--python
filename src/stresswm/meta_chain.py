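"""Posterior-as-prior chaining of study effects with per-step Bayes factors.

The meta-analysis walks an ordered list of studies.  The first study acts
as the anchoring prior: its published (mean difference, SEM) both receives
a Bayes factor against a vague prior (half of an assumed maximum plausible
effect) and becomes the chaining prior for the second study.  From then on
each step's conjugate posterior is the next step's prior, and the BF prior
scale follows the "half the maximum likely effect" rule: half the absolute
first-study effect at step 1, and half the magnitude of the numerically
greater endpoint of the previous posterior's 95% credible interval at
later steps.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .bayes_engine import (
    BFResult,
    PosteriorSummary,
    PriorSpec,
    bayes_factor,
    conjugate_update,
)
from .effect_estimation import EffectEstimate

__all__ = ["ChainStep", "ChainResult", "run_chain", "render_report", "chains_to_frame"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChainStep:
    """One iteration of the chain.

    ``posterior`` is ``None`` only at step 0, where the first study is the
    prior of the chain and no update happens.
    """

    step_index: int
    prior_mean: float
    prior_sd: float
    likelihood: EffectEstimate
    posterior: Optional[PosteriorSummary]
    bf_prior_scale: float
    bf: BFResult
    cumulative_n: int


@dataclass(frozen=True)
class ChainResult:
    contrast: str
    outcome: str
    steps: tuple

    @property
    def final_posterior(self) -> PosteriorSummary:
        return self.steps[-1].posterior

    @property
    def final_bf(self) -> BFResult:
        return self.steps[-1].bf


def run_chain(
    effects: Sequence[EffectEstimate],
    initial_max_effect: float,
    level: float = 0.95,
) -> ChainResult:
    """Run the iterative meta-analysis over ordered study effects.

    Parameters
    ----------
    effects:
        Studies in chaining order; the first is the anchoring prior study.
    initial_max_effect:
        Assumed maximum plausible group difference for the first study's
        BF; half of it is the vague prior's SD.
    """
    if len(effects) == 0:
        raise ValueError("need at least one effect")
    if not initial_max_effect > 0:
        raise ValueError("initial_max_effect must be positive")

    first = effects[0]
    steps = []
    scale0 = 0.5 * initial_max_effect
    bf0 = bayes_factor(first.mean_diff, first.sem, PriorSpec("normal", scale0))
    cum_n = first.n_total
    steps.append(
        ChainStep(
            step_index=0,
            prior_mean=0.0,
            prior_sd=scale0,
            likelihood=first,
            posterior=None,
            bf_prior_scale=scale0,
            bf=bf0,
            cumulative_n=cum_n,
        )
    )

    prior_mean, prior_sd = first.mean_diff, first.sem
    previous_posterior: Optional[PosteriorSummary] = None
    for index, effect in enumerate(effects[1:], start=1):
        if index == 1:
            scale = 0.5 * abs(first.mean_diff)
            if scale == 0.0:
                warnings.warn(
                    "first study's mean difference is zero; falling back to "
                    "half the assumed maximum effect for the BF prior scale",
                    RuntimeWarning,
                    stacklevel=2,
                )
                scale = 0.5 * initial_max_effect
        else:
            scale = 0.5 * abs(previous_posterior.greater_endpoint)
        bf = bayes_factor(effect.mean_diff, effect.sem, PriorSpec("normal", scale))
        posterior = conjugate_update(
            prior_mean, prior_sd, effect.mean_diff, effect.sem, level
        )
        cum_n += effect.n_total
        steps.append(
            ChainStep(
                step_index=index,
                prior_mean=prior_mean,
                prior_sd=prior_sd,
                likelihood=effect,
                posterior=posterior,
                bf_prior_scale=scale,
                bf=bf,
                cumulative_n=cum_n,
            )
        )
        prior_mean, prior_sd = posterior.mean, posterior.sd
        previous_posterior = posterior

    if len(steps) > 1:
        log.debug(
            "chain %s/%s: final posterior %.3f (%.3f), final BF %.3f",
            first.contrast, first.outcome,
            steps[-1].posterior.mean, steps[-1].posterior.sd, steps[-1].bf.bf10,
        )
    return ChainResult(contrast=first.contrast, outcome=first.outcome, steps=tuple(steps))


def _evidence_marker(bf10: float) -> str:
    if bf10 > 3:
        return "†"  # dagger: evidence favours H1
    if bf10 < 1 / 3:
        return "‡"  # double dagger: evidence favours H0
    return ""


def chains_to_frame(chains: Sequence[ChainResult]) -> pd.DataFrame:
    """Flatten chain results into one row per step."""
    rows = []
    for chain in chains:
        for step in chain.steps:
            post = step.posterior
            rows.append(
                {
                    "contrast": chain.contrast,
                    "outcome": chain.outcome,
                    "step": step.step_index,
                    "study_label": step.likelihood.study_label,
                    "cumulative_n": step.cumulative_n,
                    "prior_mean": round(step.prior_mean, 2),
                    "prior_sd": round(step.prior_sd, 2),
                    "likelihood_mean": round(step.likelihood.mean_diff, 2),
                    "likelihood_sem": round(step.likelihood.sem, 2),
                    "posterior_mean": None if post is None else round(post.mean, 2),
                    "posterior_sd": None if post is None else round(post.sd, 2),
                    "ci_lower": None if post is None else round(post.ci_lower, 2),
                    "ci_upper": None if post is None else round(post.ci_upper, 2),
                    "bf": round(step.bf.bf10, 2),
                    "bf_prior_scale": round(step.bf_prior_scale, 2),
                    "evidence": _evidence_marker(step.bf.bf10),
                }
            )
    return pd.DataFrame(rows)


def render_report(chains: Sequence[ChainResult]) -> str:
    """Human-readable tables, one block per chain, values at 2 decimals."""
    frame = chains_to_frame(chains)
    out = io.StringIO()
    for (contrast, outcome), block in frame.groupby(["contrast", "outcome"], sort=False):
        out.write(f"== {contrast} / {outcome} ==\n")
        display = block.drop(columns=["contrast", "outcome"]).copy()
        display["bf"] = [
            f"{bf:.2f}{marker}" for bf, marker in zip(block["bf"], block["evidence"])
        ]
        display = display.drop(columns=["evidence"])
        out.write(display.to_string(index=False, na_rep=""))
        out.write("\n\n")
    out.write("† evidence favours H1 (BF > 3); ‡ evidence favours H0 (BF < 1/3)\n")
    return out.getvalue()
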