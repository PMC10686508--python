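"""The task/questionnaire simulator: structure, calibration, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from stresswm.scales import LESS
from stresswm.synthetic_data import (
    ParticipantMeta,
    SimConfig,
    generate_life_events,
    generate_responses,
    generate_sequence,
    generate_study,
    null_config,
)


def _two_back_rescan(stimuli):
    """Independent comparator: a trial is a target iff its stimulus equals
    the stimulus two positions earlier in the same block."""
    flags = []
    for i, stim in enumerate(stimuli):
        flags.append(i >= 2 and stim == stimuli[i - 2])
    return flags


class TestGenerateSequence:
    def test_standard_run_counts(self, rng):
        seq = generate_sequence(3, 40, 13, rng)
        assert len(seq) == 120
        assert seq["is_target"].sum() == 39
        assert (seq.groupby("block")["is_target"].sum() == 13).all()
        assert set(seq["stimulus"]) <= {1, 2, 3, 4}

    def test_first_two_trials_never_targets(self, rng):
        seq = generate_sequence(3, 40, 13, rng)
        first_two = seq[seq["trial_index"] <= 2]
        assert not first_two["is_target"].any()

    def test_flags_match_independent_rescan(self, rng):
        seq = generate_sequence(3, 40, 13, rng)
        for _, block in seq.groupby("block"):
            oracle = _two_back_rescan(block["stimulus"].tolist())
            assert block["is_target"].tolist() == oracle

    def test_zero_targets(self, rng):
        seq = generate_sequence(1, 3, 0, rng)
        assert not seq["is_target"].any()

    def test_infeasible_target_count(self, rng):
        with pytest.raises(ValueError):
            generate_sequence(1, 40, 39, rng)


def _participant(hit=0.8, fa=0.1, rt=700.0):
    return ParticipantMeta(
        participant_id="p1", study_label="S", age_group="young", age_years=25,
        sex="f", scale_name="LESS", life_events_score=500,
        true_hit_prob=hit, true_fa_prob=fa, true_rt_location_ms=rt,
    )


class TestGenerateResponses:
    def test_degenerate_probabilities(self, rng):
        seq = generate_sequence(3, 40, 13, rng)
        trials = generate_responses(seq, _participant(hit=1.0, fa=0.0), rng)
        target = trials["is_target"]
        assert trials.loc[target, "responded"].all()
        assert not trials.loc[~target, "responded"].any()
        assert trials.loc[target, "rt_ms"].between(0, 3000, inclusive="right").all()
        assert trials.loc[~target, "rt_ms"].isna().all()

    def test_empirical_rates_match_binomial(self, rng):
        hits = fas = targets = nontargets = 0
        seq = generate_sequence(3, 40, 13, rng)
        for _ in range(200):
            trials = generate_responses(seq, _participant(), rng)
            target = trials["is_target"]
            hits += trials.loc[target, "responded"].sum()
            fas += trials.loc[~target, "responded"].sum()
            targets += int(target.sum())
            nontargets += int((~target).sum())
        for count, n, p in ((hits, targets, 0.8), (fas, nontargets, 0.1)):
            se = np.sqrt(p * (1 - p) / n)
            assert count / n == pytest.approx(p, abs=3 * se)

    def test_rt_mean_matches_location(self, rng):
        seq = generate_sequence(3, 40, 13, rng)
        rts = []
        for _ in range(200):
            trials = generate_responses(seq, _participant(rt=700.0), rng)
            rts.extend(trials["rt_ms"].dropna().tolist())
        rts = np.asarray(rts)
        se = rts.std() / np.sqrt(len(rts))
        assert rts.mean() == pytest.approx(700.0, abs=3 * se)


class TestGenerateLifeEvents:
    def test_boundaries(self, rng):
        assert not generate_life_events(LESS, 0, rng).any()
        assert generate_life_events(LESS, LESS.max_score, rng).all()

    def test_out_of_range_target(self, rng):
        with pytest.raises(ValueError):
            generate_life_events(LESS, LESS.max_score + 1, rng)

    def test_cohort_median_tracks_target(self, rng):
        """A cohort generated at the pooled LESS median location should
        have a sample median within 10% of 577."""
        scores = [
            generate_life_events(LESS, 577, rng).astype(int) @ np.array(LESS.weights)
            for _ in range(300)
        ]
        assert np.median(scores) == pytest.approx(577, rel=0.10)


class TestGenerateStudy:
    def test_deterministic_under_seed(self, tmp_path):
        cfg = SimConfig(seed=7, cells=(("S", "young", 8), ("S", "older", 8)))
        a = generate_study(cfg)
        b = generate_study(cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        # byte-identical CSV exports
        a[1].to_csv(tmp_path / "a.csv", index=False)
        b[1].to_csv(tmp_path / "b.csv", index=False)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_trial_structure_invariants(self, small_study):
        participants, trials = small_study
        per_part = trials.groupby("participant_id")["is_target"].agg(["sum", "count"])
        assert (per_part["sum"] == 39).all()
        assert (per_part["count"] == 120).all()
        per_block = trials.groupby(["participant_id", "block"])["is_target"].sum()
        assert (per_block == 13).all()
        responded = trials["responded"]
        assert trials.loc[responded, "rt_ms"].between(0, 3000, inclusive="right").all()
        assert trials.loc[~responded, "rt_ms"].isna().all()

    def test_participant_metadata_invariants(self, small_study):
        participants, _ = small_study
        young = participants[participants["age_group"] == "young"]
        older = participants[participants["age_group"] == "older"]
        assert (young["scale_name"] == "LESS").all()
        assert (older["scale_name"] == "SRRS").all()
        assert young["age_years"].between(18, 35).all()
        assert older["age_years"].between(60, 85).all()
        assert participants["life_events_score"].ge(0).all()
        assert young["life_events_score"].le(1849).all()
        assert older["life_events_score"].le(1466).all()

    def test_negative_interaction_lowers_older_high_cell(self):
        """With a -10 pp interaction the older/high-stress cell has the
        lowest expected accuracy of the four."""
        from stresswm.nback_scoring import score_participants

        cfg = null_config(
            seed=11,
            interaction_effect_acc=-10.0,
            cells=(("S", "young", 120), ("S", "older", 120)),
        )
        participants, trials = generate_study(cfg)
        scores = score_participants(trials).merge(
            participants[["participant_id", "age_group", "stress_group_true"]],
            on="participant_id",
        )
        cell_means = scores.groupby(["age_group", "stress_group_true"])[
            "percent_correct"
        ].mean()
        assert cell_means[("older", "high")] == cell_means.min()

    def test_null_config_cells_differ_only_by_noise(self):
        cfg = null_config(seed=3, cells=(("S", "young", 80), ("S", "older", 80)))
        participants, trials = generate_study(cfg)
        from stresswm.nback_scoring import score_participants

        scores = score_participants(trials).merge(
            participants[["participant_id", "age_group", "stress_group_true"]],
            on="participant_id",
        )
        grouped = scores.groupby(["age_group", "stress_group_true"])["percent_correct"]
        means, sems = grouped.mean(), grouped.sem()
        spread = means.max() - means.min()
        assert spread < 4 * sems.max()

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            SimConfig(baseline_hit_prob=1.2)
        with pytest.raises(ValueError):
            SimConfig(cells=(("S", "young", 1),))
        with pytest.raises(ValueError):
            SimConfig(rt_location_ms=3500)

    def test_effects_replace_helper(self):
        cfg = null_config(seed=5)
        assert cfg.age_effect_acc == 0.0
        assert dataclasses.replace(cfg, seed=9).seed == 9
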