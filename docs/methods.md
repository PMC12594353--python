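# Methods

This note documents the models, the sampler, the synthetic-data generator,
and the numerical and design choices behind `revlearn`, in the package's own
words.  Empirical statements below are limited to what the test suite and
`scripts/acceptance.py` actually compute.

## Task environment

A block is a sequence of `n_trials = 135` two-option trials.  One option is
latently *correct*; its identity flips at reversals.  Volatility fixes the
segment structure — low: 4 segments of 30–40 trials (3 reversals); high: 8
segments of 15–20 trials (7 reversals).  The high-volatility segment count is
pinned to 8 so the reversal count is exactly 7: the 15–20 range alone would
admit 7–9 segments over 135 trials, and the design intends a doubling of the
reversal rate.

Segment lengths are drawn **uniformly over the exact set of constrained
integer compositions** of 135.  Rather than rejection sampling, a
dynamic-programming count table (`count[i][s]` = number of ways i segments
can sum to s) drives sequential sampling, which is exactly uniform,
deterministic given the seed, and needs no retry cap.

Noise fixes the reward contingency: the correct option carries the reward on
75% (low) or 65% (high) of trials.  Contingencies are *constructed*, not
Bernoulli-sampled: each segment gets exactly `round(p × length)` rewarded-
correct trials (round-half-to-even, unbiased across segments) at shuffled
positions.  Because per-segment counts are integers, the realized average
contingency across random segment lengths is ≈ 74.8% / 64.9% rather than
exactly 75 / 65; the acceptance script reports the realized values.
Outcomes of the two options are anti-correlated by construction: the outcome
of choosing A is always the negation of choosing B.

Sessions consist of four blocks, one per condition (LVLN, LVHN, HVLN, HVHN).
Per-condition schedules are a function of `(condition, shared_seed)` only, so
all subjects given one seed face identical trial sequences (a shared-sequence
protocol).  The admissible block orders implement the two counterbalancing
schemes (4 orders: volatility fixed pairwise, noise alternating; plus 4
reversed-scheme orders for the extended design).  The design fixes the
schemes, not the literal order tuples; the constructed sets satisfy them.

## Learning models

All six models share value updating by prediction error and a softmax choice
rule.  Outcomes are coded +1 (reward) / −1 (punishment); values start at 0 at
each block start and never carry across blocks (blocks are separate
conditions).  Parameters: learning rates η, η⁺, η⁻ and the EWA parameters
φ (payoff decay) and ρ (experience decay) in (0, 1); value sensitivity
β in (0, 10); indecision point α unbounded.  Bounds are treated as closed at
the edges in direct evaluation (η = 0 or β = 0 are well-defined degenerate
policies); the hierarchical transforms keep posterior draws interior.

* **RW** — `V_c ← V_c + η(O − V_c)`; `p(A) = 1/(1+e^{β(V_B−V_A)})`.
* **RP** — as RW with η⁺ after rewards, η⁻ after punishments.
* **EWA** — experience weights `n_c ← n_c ρ + 1`, then
  `V_c ← (V_c φ n_c,prev + O)/n_c`; only the chosen option updates.
* **FU** — RW plus a fictitious update of the unchosen option with outcome
  −O.  The printed form of this update references the *chosen* option's
  previous value inside the prediction error; the default here uses the
  unchosen option's own value (the standard fictitious rule, and the one
  under which RP/RW nesting identities hold).  The other reading is
  available via `fictitious_pe="chosen"`.
* **FU-RP** — fictitious update with split learning rates.  The unchosen
  update's rate is selected by the sign of the *obtained* outcome and shared
  across both updates (`rate_select="factual"`, the convention of the
  hierarchical fitting packages this design follows); selecting by the
  fictitious outcome's sign is available as `"per-option"`.
* **FU-RP-IP** — FU-RP with a softmax midpoint offset:
  `p(A) = 1/(1+e^{β(α−(V_A−V_B))})`.

Nesting identities (RP = RW at η⁺ = η⁻; FU-RP = FU likewise; FU-RP-IP =
FU-RP at α = 0) are enforced by tests, as is agreement of every likelihood
path — reference implementation and compiled kernels — with a deliberately
literal per-trial oracle to 1e-10.

Missing responses (choice coded 0) contribute no likelihood term and trigger
no state update; a missing response also breaks win-stay/lose-shift chains.

## Hierarchical estimation

One fit covers one (model, condition, group) cell.  Subject parameters use a
non-centered parameterization: `θ_ik = T_k(μ_k + σ_k z_ik)` with
`z_ik ~ N(0,1)`, where `T_k` is the standard-normal CDF scaled to the bound
(×10 for β) and the identity for α.  Priors: `μ_k ~ N(0,1)` (centring
learning rates at 0.5 and β at 5 prior-predictively); `σ_k ~ half-N(0, 0.2)`
for bounded parameters and `half-N(0, 1)` for α — the convention of the
hierarchical RL fitting packages this mirrors; both scales are configurable
and echoed in the fit's provenance.

Sampling is Hamiltonian Monte Carlo with analytic gradients.  The likelihood
gradient is an exact forward-mode recursion per model family (dV/dθ carried
through every learning step), compiled with numba; a finite-difference test
pins it.  The engine uses dual-averaging step-size adaptation to a 0.8
acceptance target, a diagonal mass matrix estimated from a mid-warmup window
(variances regularized Stan-style toward 1e-3), jittered trajectory lengths
(≈1.2 in the whitened metric) against periodic orbits, and an energy-error
divergence guard.  Trajectories are capped at 24 leapfrog steps until the
mass matrix is adapted: before adaptation the metric is badly scaled and long
trajectories buy nothing.  Chains are independent and seeded from a
`SeedSequence`; identical seeds reproduce draws exactly.

Two schedules are built in: a full profile (3 chains × 4,000 with
2,000 discarded — the estimator default) and a reduced "desk" profile
(3 × 1,000 + 1,000) used throughout the test suite and the acceptance
script; sizes there were chosen so the full suite runs on one core in
minutes while leaving the statistical claims intact.

Diagnostics: split-chain potential scale reduction (R̂), computed over every
sampled dimension, with a 1.1 gate — exceeding it flags the fit and warns,
never silently passes; an unconverged fit refuses posterior predictive checks
unless forced.  Model comparison uses PSIS-LOO (via `arviz.psislw`) on the
per-subject-per-trial pointwise log-likelihood, with `LOOIC = −2·elpd_loo`
exactly, Pareto-k > 0.7 counted and warned about, and LOOIC-difference SEs
from paired pointwise contributions.  For long datasets the pointwise matrix
is computed on up to 1,000 evenly thinned, chain-balanced draws to bound
memory.

## Posterior decision rules

Condition and group effects are judged on group-level posterior differences:
the 89% HDI (shortest interval containing ⌈0.89 n⌉ sorted draws), the
probability of direction, and the ±0.1 ROPE with the 2.5% rejection rule.
Cross-fit differences pair draws after a seeded shuffle (the two posteriors
are independent; any pairing is valid, so it must merely be reproducible);
within-fit contrasts pair draws directly.  The ROPE is applied by default to
the raw difference on the natural scale (learning rates and α are already
≈unit-scaled; β differences are compared on its (0, 10) scale), with
`standardize=True` dividing by the posterior SD first, and a flag restricting
the computation to the draws inside the 89% HDI — the two readings of the
rule are both defensible, so both are available; the whole-posterior reading
is the default.

## Synthetic cohorts

The generator emulates the experimental design's structure: trait scores truncated-normal
(mean 50.75, SD 10.21 on the 20–80 STAI-T range), tertile split (inclusive-
rank thresholds; scores at a threshold join the outer group, matching the
"≤ low cut / ≥ high cut" convention) or median split; block orders assigned
round-robin; per-(group, condition) generating parameters specified as
natural-scale mean ± SD and mapped to the unconstrained scale (probit mean,
delta-method SD) so draws always respect bounds; optional trait couplings act
linearly on that scale.  Default generating values are this package's
choices: plausible for the task class, reproducing the qualitative condition
structure (volatility-driven learning-rate increases under low noise, higher
β under low noise, a slightly more exploitative high-anxiety group).  They
are **not** fitted values from any dataset, and the default agents are
somewhat more exploitative than typical online participants (higher win-stay
rates); passing tests on these cohorts demonstrates that the machinery
recovers what generated the data, not that real populations behave this way.
The generator also omits reaction times, attention lapses, dropout, and
demographic structure.

## Validation protocol

Posterior predictive checks re-simulate every subject on the actual schedule
from joint posterior draws (all subjects taken from the same draw, preserving
posterior correlation) and compare trial-aligned choice proportions,
accuracy, win-stay and lose-shift against their simulated central bands.
Parameter recovery runs by two routes — fresh subjects drawn from group-level
hyperparameters, or subjects fixed at fitted individual medians — then refits
and reports generating-mean HDI coverage (scored on the unconstrained scale,
where the generating values live), true-versus-recovered subject
correlations, and the shrinkage ratio (recovered subject spread over
generating spread, < 1 under hierarchical pooling).

## Numerical details worth knowing

* Log-probabilities use the stable log-logistic form; the per-trial kernels
  compute `log σ(m)` and its weight from a single exponential.
* The likelihood kernels accept a per-trial reset flag; the first trial of
  every block resets values, experience weights, and their derivative
  carries.  Fitting concatenated multi-block data without these resets biases
  learning rates upward and β downward (the agent's fresh values at block
  starts look like forgetting) — the recovery suite was the canary for this.
* `exp(log σ)` is clipped at e±200 inside the posterior density so wild
  warmup proposals overflow nothing; such moves are rejected on energy.
* Sample-HDI endpoints converge at a cube-root rate; endpoint tests average
  several independent samples instead of pretending single-sample precision.
* The Fisher-z power calculator includes the `r/(2(n−1))` bias correction,
  matching the convention of the standard power-analysis packages (e.g.,
  n = 29 for r = .5, α = .05 two-sided, power .8).
* Exclusion thresholds: the accuracy rule reports both the unrounded
  threshold (e.g. 41.165%) and the integer percent (41%); exclusions use the
  unrounded value.  The sample SD threshold is computed on the full sample,
  before RT-based exclusions.  All trial-count rules use strict inequalities,
  so a subject exactly at a boundary (27 slow trials, 54 same-colour choices
  of 540) is retained.

## Known limitations

* The sampler is plain adaptive HMC, not NUTS; very small cells (2–4
  subjects) can need a few hundred extra warmup draws for R̂ < 1.05.
* PSIS-LOO treats subject-trials as conditionally independent observations
  given the parameters — standard for this model class, but k̂ diagnostics
  flag influential early-block trials more often than late ones.
* EWA values are not confined to [−1, 1] (experience weighting can
  transiently amplify), so the convexity argument for the delta-rule models
  does not apply to it.
* Recovery claims are calibrated at the simulated scales (up to 40 subjects ×
  540 trials); much larger cohorts only improve them, but tiny cells are
  honestly hard and the R̂ gate will say so.
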