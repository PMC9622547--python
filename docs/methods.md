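# Methods

This note documents the models, procedures, parameter choices and
numerical decisions behind `revlearn`, and the limits of what its
synthetic-data results demonstrate.

## Task environments

**Serial reversal.**  The default task has 11 stages: discrimination,
first reversal, SRL1 ×5 (all 80/20, 1-credit wins) and SRL2 ×4 (80/40,
wins of 2 or 6 credits with equal probability).  Criterion is 6
consecutive correct choices; the target reverses at every boundary;
reward draws are independent Bernoulli per trial (no debiasing
schedule — only marginal probabilities are specified by the procedure).
No cap on stage length is stated by the original procedure, but some
participants evidently did not finish the late stages, so stages carry a
configurable `max_trials` (default 80); a truncated stage marks the
session incomplete from that stage and, by default, later stages are not
run.  Fixed-length estimation schedules (`build_fixed_length_task`, 25
blocks × 20 trials) instead advance on truncation so every stage
contributes exactly 20 trials.  Stimulus/side counterbalancing is
collapsed to option indices 0/1; the initial target is configurable.

**Devaluation.**  Instrumental training simulates token-earning rounds
(each a uniform draw of 5–10 consecutive responses) with a comprehension
question after every third round; training ends at six consecutive
correct questions or a question cap.  Question accuracy is a Bernoulli
parameter of the simulated responder; question content is not modelled.
The choice test draws per-block response counts from Poisson processes
with given valued/devalued rates over 10 × 12 s blocks.  The Poisson
choice is a modelling contract for generating plausible free-operant
counts, not a claim about participants' motor process.

Every stochastic operation takes an explicit `numpy.random.Generator`;
nothing uses global random state.

## Models and likelihoods

EWA keeps per-option attractions and experience weights, both starting
at zero, with only the chosen option updating (`n_c ← ρ n_c + 1`,
`A_c ← (φ n_old A_c + r)/n_new`); the first update therefore reduces to
`A_c = r`.  A shared-experience-weight variant exists in the literature;
this implementation uses per-option weights, the convention of the
reversal-learning model family it follows.  The RP model updates the
chosen option toward the payoff with the valence-matched rate and,
fictively, the unchosen option toward the negated payoff with the
opposite-valence rate; a chosen-only switch is provided because the
original equations are not printed in the source literature.

Payoff coding: wins → +1, losses → −1 by default, regardless of credit
magnitude (the standard coding in this model family); an optional
magnitude coding divides win credits by the stage's mean win credit.
Both are shipped because the original analysis does not state how 2-vs-6
credit wins entered the models.

The softmax is computed via a max-shift (log-sum-exp), so likelihoods
are finite for any β ≤ the cap.  `log_likelihood` is an inlined scalar
loop (it sits inside the optimizer); its correctness is certified
against an independent brute-force stepping oracle at 1e−10 on random
sessions.

## Fitting

MAP with multi-start L-BFGS-B replaces hierarchical Bayesian MCMC: the
downstream quantities (group parameter summaries, simulation inputs) are
point estimates, and MAP keeps the artifact light.  Externally fitted
posterior means can be injected via the parameter-file format.
Transforms: logit for unit-interval parameters (bounded at ±8 on the
unconstrained scale), log for β with an upper bound of ln 20 — the β cap
avoids softmax-saturation plateaus.  Priors on the unconstrained scale:
N(0, 1.5²) for logit parameters, N(ln 2, 1) for log β.  The first start
is the prior mode (so single-start fits are deterministic); further
starts are prior draws.  Ties between equal-objective starts (within
1e−9) break by lexicographic parameter order.  A subject where no start
converges is returned flagged, not raised; sessions under 20 trials are
rejected.

Recovery at the certification scale (500-trial sessions, 40 subjects,
true values drawn φ∈[0.3,0.9], ρ∈[0.1,0.9], β∈[0.75,8]) reaches Pearson
r ≈ 0.97 (φ), 0.89 (ρ), 0.81 (β).  The 11-stage task itself yields only
one-to-a-few hundred trials and visibly noisier recovery — the recovery
report exposes this by design, and group-level claims on the synthetic
cohort rest on group means over 18–28 subjects, not individual fits.

## Behaviour metrics

Trials-to-criterion counts the criterion run itself (minimum observable
value 6).  Perseverative errors are incorrect choices among the first 6
trials after each reversal (window clipped at stage length).
Win-stay/lose-shift are proportions over applicable consecutive-trial
pairs; pairs spanning stage boundaries count by default, because
reversals are silent and the stimulus pair never changes (a within-stage
switch exists).  Win-stay by win magnitude is computed where credits
vary, i.e. the SRL2 phase.  Phase summaries (first reversal, SRL1, SRL2)
are per-stage means; incomplete stages are excluded from those means and
flagged, but their observed trials still enter the WSLS proportions.
Proportions always carry denominators and are `None` (never 0/0) when no
pair is applicable.  Devaluation metrics: rates are total responses over
total test time; bias is valued/(valued+devalued), undefined when no
responses occurred.

## Subgrouping

Ward-linkage hierarchical clustering, cut at k = 2 (fixed by design), on
z-scored preference ratio and valued response rate, pooled across
groups.  z-scores use the sample standard deviation (ddof = 1).
Zero-variance features and cohorts with identical subjects are rejected.
The higher-mean-bias cluster is labelled intact, and the empirical
boundary is reported as the interval (max impaired bias, min intact
bias).  Subjects with undefined bias are excluded and listed in the
result.  scipy's Ward implementation breaks merge ties by lowest cluster
index, making labels deterministic and order-invariant in practice.

## Simulation study

Nine conditions: three group baselines plus all single and pair
substitutions of impaired-group φ/ρ/β into the control background (the
triple substitution *is* the impaired baseline and is not duplicated).
Each condition simulates 20 agents (the study-design default) with the
group's *point* parameters — no within-group dispersion, matching the
described design; dispersion can be added through the cohort module for
sensitivity analyses.  Agents advance past truncated stages, and a
truncated stage scores `max_trials` as its trials-to-criterion — a
deliberate, conservative divergence from the behaviour-metrics exclusion
policy, needed because strongly impaired parameter sets truncate often
and exclusion would bias their summaries downward.  Outcomes are SRL1
mean trials-to-criterion and SRL1 win-stay per agent; comparisons to the
control condition use two-sided Dunnett many-to-one tests
(`scipy.stats.dunnett`; the quadrature seed is fixed from the study rng
so results are bit-reproducible given the seed).  With identical
parameter sets in all conditions, the familywise false-positive rate per
metric is ≈ 5% over 200 seeds (measured 0.050).

## Synthetic cohorts

The generator's defaults define the study conditions:

* Cohort structure: 34 controls (28 intact / 6 impaired goal-directed
  action) and 43 psychosis subjects (18 intact / 25 impaired).
* Devaluation bias: two-component Beta mixture — intact mean 0.95
  (concentration 60), impaired mean 0.50 (concentration 40); psychosis
  intact 0.93.  These place the component modes on either side of the
  empirical boundary region (~0.72–0.81) without assuming its exact
  location.  Response rates: per-subject total rate lognormal around
  1.0/s, split by the subject's bias.  Devalued-token ratings drop by
  ~3 Likert points for intact and ~1 for impaired subjects; probe
  accuracy 0.95.
* EWA parameters per (group × component) cell, with subject-level sd
  (0.05, 0.05, 0.4):

  | cell | φ | ρ | β |
  |---|---|---|---|
  | control intact | 0.70 | 0.30 | 3.5 |
  | psychosis intact | 0.55 | 0.35 | 3.0 |
  | impaired (both groups) | 0.55 | 0.65 | 1.5 |

  These values are configuration chosen to reproduce the qualitative
  group *orderings* of the fitted clinical cohorts (psychosis: lower φ;
  impaired additionally: higher ρ, lower β) — the original per-group
  estimates are not published.  They were selected by a pilot grid over
  candidate sets, requiring that the impaired baseline shows both
  deficits, that the ρ+β substitution reproduces both, and that no
  single-parameter substitution does, robustly across seeds at n = 20
  agents; the selected set satisfied all three in 8/8 pilot seeds and
  the pattern survives the full generate → cluster → fit → simulate
  pipeline.

**What the synthetic results show — and don't.**  Passing pipelines on
these cohorts certify that the machinery is correct and that the
published qualitative pattern is *reachable* under parameter
configurations with the published orderings.  They do not reproduce the
original cohort's numbers: real participants are not EWA agents with
normal parameter dispersion, real bias distributions need not be clean
Beta mixtures, and real response rates correlate with symptoms and IQ in
ways the generator does not model.  Quantitative claims here are limited
to task/procedure constants and estimator properties.

## Problem sizes

Defaults throughout are desk-scale choices: 100,000 draws for
contingency checks, 40 × 500-trial sessions for recovery certification,
200 seeds × 9 conditions × 20 agents for error-rate measurement, and the
77-subject default cohort for the end-to-end replication.  The whole
suite runs in about two minutes on one core.
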