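# Methods

## The analysis model

The package implements an *iterative Bayesian meta-analysis* of a small
series of cross-sectional studies that each compare 2-back working-memory
performance between groups: young vs. older adults, low vs. high cumulative
life stress, the stress contrast within each age group, and the
age-by-stress interaction.  Each study contributes one effect per contrast
and outcome — a group mean difference `d` (percentage points of accuracy,
or milliseconds of hit reaction time) with its standard error `s` — and the
observed effect is modelled as normal, `d ~ N(theta, s^2)`.

**Posterior-as-prior chaining.**  The series is ordered; the first
(anchoring) study's `(d, s)` acts as the prior for the second study.  With
a normal prior `N(m0, s0^2)` and a normal likelihood, the posterior is
conjugate: precisions add, and the posterior mean is the precision-weighted
average.  Each step's posterior becomes the next step's prior, so the final
posterior is the fixed-effect combination of all studies (order-invariant,
which the tests assert).  Credible intervals are central normal intervals,
`mean ± 1.96 sd` at the 95% level.

**Bayes factors.**  At every step a Bayes factor compares the point null
`theta = 0` against an alternative whose prior on `theta` is zero-centred
with a scale set by the "half the maximum likely effect" convention:

- step 0: half of an assumed maximum plausible group difference (a
  configurable per-chain constant, e.g. 5 pp for a 10 pp assumed maximum);
- step 1: half the absolute anchoring effect;
- step k >= 2: half the magnitude of the *numerically greater* endpoint of
  the previous posterior's 95% interval (the "maximum likely effect size",
  even when the whole interval is negative).

For a normal alternative the marginal likelihood has the closed form
`N(d; 0, sqrt(s^2 + scale^2))`; BFs are graded with the conventional
3 / 10 / 30 / 100 thresholds (anecdotal, substantial, strong, very strong,
extreme), mirrored below 1 for the null.

**Robustness (sensitivity) sweep.**  A BF is considered robust when
normal, Student-t(df = 2) and Cauchy (t, df = 1) alternatives at the same
scale land in the same evidence category.  The heavy-tailed marginals are
computed by adaptive quadrature (relative tolerance 1e-10, geometric
breakpoints resolving both the prior and likelihood length scales, and a
doubled-range check against silent tail truncation).  For the sweep the
heavy-tailed priors are restricted to ±10 scale units and renormalised.
This bounded support mirrors the grid-based calculators traditionally used
for this style of analysis, which represent the alternative prior over
about ten scale units, and is scientifically sensible: an unbounded Cauchy
alternative places non-trivial prior mass on absurd effect sizes.
`bayes_factor` itself defaults to proper (untruncated) priors; the bounded
variant is selected via `PriorSpec.support_halfwidth`.

## Scoring

2-back runs are 120 trials in 3 blocks of 40, with 13 targets and 27
non-targets per block and a 3000 ms response window.  Responses partition
into hits / misses / false alarms / correct rejections per block.

- **Percent correct** = (hits + correct rejections) / 120 × 100, always
  over all trials.
- **d′** = Φ⁻¹(H) − Φ⁻¹(F) per block, with the standard 1/(2n) edge
  corrections (n = 13 targets for a perfect hit rate, n = 27 non-targets
  for a zero false-alarm rate; the symmetric edges are corrected the same
  way).  Blocks with d′ ≤ 0 indicate response confusion or bias and are
  excluded from the per-participant d′ average (arithmetic mean of the
  retained blocks); a participant with no positive-d′ block is flagged and
  excluded from accuracy aggregation.
- **Reaction time**: hit RTs only, trimmed once per participant-block to
  within 2.5 SD of their own mean (single pass — the filter is not
  re-applied to the survivors), then pooled across blocks.

Cumulative stress is the weighted sum of endorsed life events (LESS for
young adults, 36 items, 0–1849 life-change units; SRRS for older adults,
43 items, 0–1466).  Cohorts are median-split per study and age group
(optionally at one pooled median per scale); scores equal to the median go
to the low-stress group — the conservative choice when the hypothesis
predicts high-stress impairment.  A phi-correlation screen between age
group and stress group warns (without aborting) if the split confounds the
design.  PSS-10 and STAI questionnaires are scored by summation with
reverse-keyed items mapped `max + min − x` first.

## Effects

Two-group contrasts use the unpooled (Welch) standard error
`sqrt(var_A/n_A + var_B/n_B)` with sample variances; the original analyses
do not state their SEM construction, and the unpooled form is the safe
default under unequal cell sizes and variances.  The interaction contrast
`(low − high)_young − (low − high)_older` is built, by default, from
harmonic cell means with an unweighted-means standard error
`sqrt(sum of cell variances / n_h)`, `n_h` the harmonic mean of the four
cell sizes — the stated convention for uneven groups is a harmonic mean,
but the construction is not given in full, so a harmonic-cell-size variant
and a plain arithmetic variant are provided behind a flag and none of the
three is claimed to reproduce the anchoring study's printed interaction
cell, which cannot be re-derived from published summaries.  A
speed–accuracy screen (Pearson correlation between hit accuracy and mean
hit RT; a significantly positive r flags a trade-off) gates whether
accuracy conclusions should defer to RT.

## The synthetic-data generator

The generator emulates the design the analysis assumes so that the whole
pipeline is testable without any external data:

- **Cells**: four studies with the published cohort sizes (60 = 30 + 30
  anchoring; 40, 58, 58 replications).
- **Task**: per-block stimulus sequences over the digits 1–4 with exactly
  13 two-back targets placed uniformly among positions 3–40; the first two
  trials of a block are structurally non-targets; non-target stimuli avoid
  the two-back digit.
- **Responses**: independent Bernoulli per trial (hit probability on
  targets, false-alarm probability on non-targets; misses are
  non-responses and carry no RT).  Hit/FA baselines default to 0.80/0.10,
  typical 2-back operating points.  RTs are log-normal with mean
  `true_rt_location_ms` (default 700 ms, near the published online-sample
  mean) and log-scale SD 0.25, truncated at the 3000 ms window.
- **Effects**: accuracy effects in percentage points are applied
  symmetrically to the hit and correct-rejection probabilities, so the
  expected percent-correct shift equals the configured effect; RT effects
  shift the log-normal mean.  The interaction effect is added to the
  older/high-stress cell, matching the contrast's sign convention.
  Defaults are the pooled posterior estimates of the replication series
  (age 2.37 pp and −125 ms, stress 2.88 pp, interaction 0 — the
  interaction evidence was inconclusive); `null_config()` switches every
  effect off.
- **Heterogeneity**: participant-level jitter on the logit of the response
  probabilities (SD 0.5) and the log of the RT location (SD 0.15), so
  between-subject accuracy SD is ~7–8 pp rather than purely binomial,
  matching the published standard errors.
- **Life events**: each participant draws a latent score target from a
  normal per age group (young 577 ± 240, older 786 ± 170 — the pooled
  medians with IQR-matched spreads), then endorses each item independently
  with probability target/maximum, which centres the realised weighted
  total on the target.
- **Stress group truth**: the generator assigns high/low stress by
  median-splitting the *realised* scores within each study-by-age cell
  with the same tie-to-low rule the analysis uses.  A latent-score
  assignment would let endorsement noise misclassify participants around
  the median and attenuate injected stress effects relative to the groups
  the analysis actually contrasts; defining the truth on the realised
  split keeps injected effects identified.

What the generator does *not* emulate: practice trials and re-practice
rules, EEG, sequential response dependencies (fatigue, post-error
slowing), item-level life-event structure (the default LESS/SRRS weight
tables are synthetic descending ramps summing to the printed maxima — only
totals and medians matter downstream), and non-normal score distributions.
Passing recovery tests therefore show that the chain recovers effects of
the assumed form at realistic noise levels, not that real 2-back data meet
those assumptions.

## Validation scale and numerical choices

Simulation-based checks run 100 replicates of a full four-study pipeline
per condition (about a minute each on one CPU): with all effects at zero,
the final chained interaction BF stays below 3 in ≥ 90% of replicates; with
a −12.55 pp interaction injected (the anchoring study's printed effect),
the true value falls inside the final 95% credible interval in ≥ 90% of
replicates.  Observed coverage sits near the 90% bound rather than the
nominal 95% because cell variances are estimated from ~10–15 participants
and the normal likelihood ignores that estimation error — a property of
the published method itself, not of the generator.

Degenerate inputs are handled explicitly: zero-SEM observations and
non-positive prior scales are rejected; a zero anchoring effect at step 1
falls back to the vague initial scale with a warning; quadrature failure
(range-doubling disagreement) raises rather than returning a silently
truncated marginal; BFs whose log exceeds 700 are reported as infinite
rather than overflowing.  Table output rounds to 2 decimals; all internal
computation is full precision.
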