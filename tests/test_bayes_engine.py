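"""Unit and property tests for conjugate updating and Bayes factors."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stresswm.bayes_engine import (
    PriorSpec,
    _quadrature_marginal,
    bayes_factor,
    classify_bf,
    combine_effects,
    conjugate_update,
    credible_interval,
    deconvolve_update,
    robustness_sweep,
)

finite = st.floats(-50, 50)
positive = st.floats(0.1, 30)


class TestConjugateUpdate:
    @pytest.mark.parametrize(
        "prior, obs, expected",
        [
            # published age/accuracy step: prior Marshall, likelihood Study 1
            ((4.83, 1.64), (4.35, 2.42), (4.68, 1.36)),
            # published interaction/accuracy step
            ((-12.55, 2.85), (1.53, 4.65), (-8.70, 2.43)),
            # equal-precision symmetry
            ((0.0, 1.0), (0.0, 1.0), (0.0, 1 / math.sqrt(2))),
        ],
    )
    def test_examples(self, prior, obs, expected):
        post = conjugate_update(*prior, *obs)
        assert post.mean == pytest.approx(expected[0], abs=0.01)
        assert post.sd == pytest.approx(expected[1], abs=0.01)

    @given(
        mu0=finite, sd0=positive,
        effects=st.lists(st.tuples(finite, positive), min_size=2, max_size=5),
    )
    def test_order_invariance(self, mu0, sd0, effects):
        """Precision additivity: the posterior ignores the update order."""
        forward = combine_effects(mu0, sd0, effects)
        backward = combine_effects(mu0, sd0, list(reversed(effects)))
        assert forward.mean == pytest.approx(backward.mean, rel=1e-9, abs=1e-9)
        assert forward.sd == pytest.approx(backward.sd, rel=1e-9)

    @given(mu0=finite, sd0=positive, obs=finite, sem=positive)
    def test_posterior_sd_strictly_shrinks(self, mu0, sd0, obs, sem):
        post = conjugate_update(mu0, sd0, obs, sem)
        assert post.sd < min(sd0, sem)

    @given(mu0=finite, sd0=positive, obs=finite, sem=positive)
    def test_deconvolve_roundtrip(self, mu0, sd0, obs, sem):
        post = conjugate_update(mu0, sd0, obs, sem)
        mean, sem_back = deconvolve_update(mu0, sd0, post.mean, post.sd)
        assert mean == pytest.approx(obs, rel=1e-7, abs=1e-7)
        assert sem_back == pytest.approx(sem, rel=1e-7)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            conjugate_update(0, 0, 1, 1)
        with pytest.raises(ValueError):
            conjugate_update(0, 1, 1, -2)


class TestCredibleInterval:
    @pytest.mark.parametrize(
        "mean, sd, expected",
        [
            (4.68, 1.36, (2.02, 7.34)),  # published age/accuracy interval
            (2.37, 1.00, (0.41, 4.33)),  # published final age/accuracy interval
            (5.0, 0.0, (5.0, 5.0)),
        ],
    )
    def test_examples(self, mean, sd, expected):
        lo, hi = credible_interval(mean, sd)
        assert lo == pytest.approx(expected[0], abs=0.01)
        assert hi == pytest.approx(expected[1], abs=0.01)

    def test_level_validation(self):
        with pytest.raises(ValueError):
            credible_interval(0, 1, level=1.5)


class TestBayesFactor:
    @pytest.mark.parametrize(
        "obs, sem, scale, expected, tol",
        [
            # published age/RT anchoring study BF with the 50 ms vague prior
            (-441.28, 109.07, 50.0, 3.77, 0.01),
            # published stress/accuracy Study 1 BF (prior = half the
            # anchoring study's effect)
            (5.77, 2.35, 1.75, 2.35, 0.01),
            # zero observation closed form: BF = sem / sqrt(sem^2 + scale^2)
            (0.0, 1.0, 1.0, 1 / math.sqrt(2), 1e-9),
        ],
    )
    def test_normal_prior_examples(self, obs, sem, scale, expected, tol):
        result = bayes_factor(obs, sem, PriorSpec("normal", scale))
        assert result.bf10 == pytest.approx(expected, abs=tol)

    @given(obs=finite, sem=positive, scale=positive)
    def test_symmetric_under_sign_flip_normal(self, obs, sem, scale):
        prior = PriorSpec("normal", scale)
        assert bayes_factor(obs, sem, prior).bf10 == pytest.approx(
            bayes_factor(-obs, sem, prior).bf10, rel=1e-12
        )

    @pytest.mark.parametrize("obs, sem, scale, df",
                             [(5.77, 2.35, 1.75, 1), (1.3, 0.4, 6.0, 2),
                              (-12.55, 2.85, 2.5, 1)])
    def test_symmetric_under_sign_flip_student_t(self, obs, sem, scale, df):
        tprior = PriorSpec("student_t", scale, df=df)
        assert bayes_factor(obs, sem, tprior).bf10 == pytest.approx(
            bayes_factor(-obs, sem, tprior).bf10, rel=1e-6
        )

    @pytest.mark.parametrize("obs, sem", [(2.0, 1.0), (-5.0, 2.5), (0.3, 0.7)])
    def test_closed_form_matches_quadrature(self, obs, sem):
        for scale in (0.5, 1.75, 10.0):
            prior = PriorSpec("normal", scale)
            closed = bayes_factor(obs, sem, prior).bf10
            from scipy.stats import norm

            quad = _quadrature_marginal(obs, sem, prior) / norm.pdf(obs, 0, sem)
            assert quad == pytest.approx(closed, rel=1e-8)

    def test_lindley_scale_limits(self):
        """BF -> 1 as the alternative collapses on the null, -> 0 as it
        spreads over an unbounded range (Lindley behaviour)."""
        for family, df in (("normal", None), ("student_t", 2)):
            tiny = bayes_factor(2.0, 1.0, PriorSpec(family, 1e-6, df=df)).bf10
            assert tiny == pytest.approx(1.0, abs=1e-5)
            huge = bayes_factor(2.0, 1.0, PriorSpec(family, 1e5, df=df)).bf10
            assert huge < 1e-3

    def test_invalid_priors(self):
        with pytest.raises(ValueError):
            PriorSpec("normal", -1.0)
        with pytest.raises(ValueError):
            PriorSpec("student_t", 1.0)  # df missing
        with pytest.raises(ValueError):
            PriorSpec("normal", 1.0, df=3)
        with pytest.raises(ValueError):
            bayes_factor(1.0, 0.0, PriorSpec("normal", 1.0))


class TestRobustness:
    def test_published_sensitivity_case(self):
        """The one printed non-robust cell: anecdotal under the normal
        prior but substantial under the heavy-tailed families."""
        res = robustness_sweep(5.77, 2.35, 1.75)
        bfs = {prior.label: bf for prior, bf in res.sweep}
        assert bfs["normal"] == pytest.approx(2.35, abs=0.01)
        assert bfs["t(df=2)"] > 3
        assert bfs["cauchy"] > 3
        assert res.verdict == "not_robust"
        assert res.discordant == ("normal",)

    def test_null_observation_is_robust(self):
        res = robustness_sweep(0.0, 1.0, 1.0)
        assert res.verdict == "robust"
        assert all(bf < 1 for _, bf in res.sweep)

    def test_heavier_tails_raise_bf_for_tail_observation(self):
        """For an observation in the prior's tail the heavier-tailed
        alternatives fare better: BF(normal) < BF(t2) <= BF(cauchy)."""
        res = robustness_sweep(5.77, 2.35, 1.75)
        bfs = [bf for _, bf in res.sweep]
        assert bfs[0] < bfs[1] <= bfs[2]


class TestClassify:
    @pytest.mark.parametrize(
        "bf, expected",
        [
            (15.99, "strong evidence for H1"),
            (1.0, "anecdotal"),
            (0.2, "substantial evidence for H0"),
            (3.08, "substantial evidence for H1"),
            (50.9, "very strong evidence for H1"),
            (200.0, "extreme evidence for H1"),
            (0.005, "extreme evidence for H0"),
        ],
    )
    def test_categories(self, bf, expected):
        assert classify_bf(bf) == expected

    @given(st.floats(1e-6, 1e6))
    def test_reciprocal_symmetry(self, bf):
        """Grading is symmetric: 1/bf swaps the hypothesis labels."""
        cat = classify_bf(bf)
        flipped = classify_bf(1.0 / bf)
        assert flipped == cat.replace("H1", "H0") if "H1" in cat else True
        if cat == "anecdotal":
            assert flipped == "anecdotal"
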