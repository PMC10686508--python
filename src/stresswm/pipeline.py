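"""End-to-end orchestration: simulate -> score -> split -> effects -> chain.

Every stage consumes and produces plain data frames (persisted as CSV when
an output directory is given), so any stage can be re-run from the
previous stage's output.  The module also ships the published study-level
effects as a fixture (``load_published_effects``), so the meta-analysis
stage can be reproduced without any simulation.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import effect_estimation, meta_chain, nback_scoring, stress_grouping
from .effect_estimation import EffectEstimate
from .meta_chain import ChainResult, chains_to_frame, render_report, run_chain
from .synthetic_data import SimConfig, generate_study

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "build_effects",
    "effects_from_frame",
    "run_chains_from_frame",
    "load_published_effects",
    "DEFAULT_INITIAL_MAX",
]

log = logging.getLogger(__name__)

#: Assumed maximum plausible group difference per (contrast, outcome), the
#: anchor for each chain's first vague BF prior (half of it is the prior
#: SD).  Taken from the published chains' stated priors.
DEFAULT_INITIAL_MAX = {
    ("age", "percent_correct"): 10.0,
    ("age", "rt_ms"): 100.0,
    ("stress", "percent_correct"): 10.0,
    ("stress", "rt_ms"): 100.0,
    ("interaction", "percent_correct"): 5.0,
    ("interaction", "rt_ms"): 50.0,
    ("stress_within_young", "percent_correct"): 10.0,
    ("stress_within_young", "rt_ms"): 25.0,
    ("stress_within_older", "percent_correct"): 25.0,
    ("stress_within_older", "rt_ms"): 75.0,
}

OUTCOME_COLUMNS = {"percent_correct": "percent_correct", "rt_ms": "mean_rt_ms"}


@dataclass
class PipelineConfig:
    sim: SimConfig = dataclass_field(default_factory=SimConfig)
    split_mode: str = "per_study"
    interaction_variant: str = "harmonic_scores"
    initial_max_effects: dict = dataclass_field(
        default_factory=lambda: dict(DEFAULT_INITIAL_MAX)
    )
    contrasts: tuple = effect_estimation.CONTRASTS
    outcomes: tuple = ("percent_correct", "rt_ms")
    out_dir: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "cells" in sim_raw:
            sim_raw["cells"] = tuple(tuple(cell) for cell in sim_raw["cells"])
        if "initial_max_effects" in raw:
            raw["initial_max_effects"] = {
                (c, o): v
                for (c, o), v in (
                    ((entry["contrast"], entry["outcome"]), entry["value"])
                    for entry in raw["initial_max_effects"]
                )
            }
        if "out_dir" in raw and raw["out_dir"] is not None:
            raw["out_dir"] = Path(raw["out_dir"])
        for key in ("contrasts", "outcomes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=SimConfig(**sim_raw), **raw)


@dataclass
class PipelineResult:
    participants: pd.DataFrame
    trials: pd.DataFrame
    scores: pd.DataFrame
    groups: pd.DataFrame
    effects: pd.DataFrame
    chains: list
    report: str


def build_effects(
    scores: pd.DataFrame,
    groups: pd.DataFrame,
    participants: pd.DataFrame,
    contrasts: Sequence[str] = effect_estimation.CONTRASTS,
    outcomes: Sequence[str] = ("percent_correct", "rt_ms"),
    interaction_variant: str = "harmonic_scores",
    study_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Study-level contrasts from scored participants and group labels."""
    merged = scores.merge(
        participants[["participant_id", "study_label", "age_group"]],
        on="participant_id",
    ).merge(groups[["participant_id", "stress_group"]], on="participant_id")
    if study_order is None:
        study_order = list(dict.fromkeys(participants["study_label"]))

    rows = []
    for study in study_order:
        chunk = merged[merged["study_label"] == study]
        for outcome in outcomes:
            col = OUTCOME_COLUMNS[outcome]
            values = chunk.dropna(subset=[col])

            def cell(age=None, stress=None):
                sel = values
                if age is not None:
                    sel = sel[sel["age_group"] == age]
                if stress is not None:
                    sel = sel[sel["stress_group"] == stress]
                return sel[col].to_numpy()

            for contrast in contrasts:
                if contrast == "age":
                    est = effect_estimation.group_contrast(
                        cell(age="young"), cell(age="older"),
                        study, "age", outcome,
                    )
                elif contrast == "stress":
                    est = effect_estimation.group_contrast(
                        cell(stress="low"), cell(stress="high"),
                        study, "stress", outcome,
                    )
                elif contrast == "stress_within_young":
                    est = effect_estimation.group_contrast(
                        cell("young", "low"), cell("young", "high"),
                        study, contrast, outcome,
                    )
                elif contrast == "stress_within_older":
                    est = effect_estimation.group_contrast(
                        cell("older", "low"), cell("older", "high"),
                        study, contrast, outcome,
                    )
                elif contrast == "interaction":
                    est = effect_estimation.interaction_contrast(
                        {
                            (age, stress): cell(age, stress)
                            for age in ("young", "older")
                            for stress in ("low", "high")
                        },
                        variant=interaction_variant,
                        study_label=study,
                        outcome=outcome,
                    )
                else:
                    raise ValueError(f"unknown contrast {contrast!r}")
                rows.append(
                    {
                        "contrast": est.contrast,
                        "outcome": est.outcome,
                        "study_label": est.study_label,
                        "mean_diff": est.mean_diff,
                        "sem": est.sem,
                        "n": est.n_total,
                    }
                )
    return pd.DataFrame(rows)


def effects_from_frame(frame: pd.DataFrame) -> list:
    """Rows of an effects table -> EffectEstimate objects (input order)."""
    return [
        EffectEstimate(
            study_label=str(row["study_label"]),
            contrast=str(row["contrast"]),
            outcome=str(row["outcome"]),
            mean_diff=float(row["mean_diff"]),
            sem=float(row["sem"]),
            n_total=int(row["n"]),
        )
        for _, row in frame.iterrows()
    ]


def run_chains_from_frame(
    effects: pd.DataFrame,
    initial_max_effects: Optional[dict] = None,
) -> list:
    """One posterior-as-prior chain per (contrast, outcome) in the table."""
    initial = dict(DEFAULT_INITIAL_MAX)
    if initial_max_effects:
        initial.update(initial_max_effects)
    chains = []
    for (contrast, outcome), block in effects.groupby(
        ["contrast", "outcome"], sort=False
    ):
        key = (contrast, outcome)
        if key not in initial:
            raise KeyError(f"no initial_max_effect configured for chain {key}")
        chains.append(run_chain(effects_from_frame(block), initial[key]))
    return chains


def load_published_effects() -> pd.DataFrame:
    """The published per-study effects for all ten chains (bundled CSV)."""
    ref = importlib.resources.files("stresswm.data") / "published_effects.csv"
    with importlib.resources.as_file(ref) as path:
        frame = pd.read_csv(path, comment="#")
    return frame.sort_values(
        ["contrast", "outcome", "step"], kind="stable"
    ).reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Simulate a multi-study dataset and run the full analysis chain."""
    participants, trials = generate_study(config.sim)
    log.info(
        "simulated %d participants / %d trials", len(participants), len(trials)
    )
    scores = nback_scoring.score_participants(trials)
    groups = stress_grouping.split_participants(participants, mode=config.split_mode)
    stress_grouping.independence_check(
        groups["age_group"].to_numpy(), groups["stress_group"].to_numpy()
    )
    effects = build_effects(
        scores,
        groups,
        participants,
        contrasts=config.contrasts,
        outcomes=config.outcomes,
        interaction_variant=config.interaction_variant,
    )
    chains = run_chains_from_frame(effects, config.initial_max_effects)
    report = render_report(chains)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        participants.to_csv(out / "participants.csv", index=False)
        trials.to_csv(out / "trials.csv", index=False)
        scores.to_csv(out / "scores.csv", index=False)
        groups.to_csv(out / "groups.csv", index=False)
        effects.to_csv(out / "effects.csv", index=False)
        chains_to_frame(chains).to_csv(out / "chains.csv", index=False)
        (out / "report.txt").write_text(report)
        log.info("wrote pipeline outputs to %s", out)

    return PipelineResult(
        participants=participants,
        trials=trials,
        scores=scores,
        groups=groups,
        effects=effects,
        chains=chains,
        report=report,
    )
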