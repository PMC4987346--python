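# Methods

## The task economy

The Iowa Gambling Task (IGT) offers four decks. Each pick pays a gain and
possibly a concurrent loss; the player experiences only the net. Decks A
and B are *bad* — any aligned 10-card run nets −$250 — while C and D are
*good* (+$250 per 10 cards). Orthogonally, A and C lose on 5 cards per 10
while B and D lose on 1, so the long-term-outcome axis and the
gain-frequency axis can be dissociated. Healthy players often prefer bad
deck B precisely because it gains frequently (the "prominent deck B"
pattern), which is what the simplified model exists to capture.

The shipped schedule (`igtpu/data/bechara_schedule.csv`) is one canonical
10-card cycle per deck tiled to 40 cards:

* A: gain 100 per card; losses −150, −300, −200, −250, −350 at cycle
  positions 3, 5, 7, 9, 10;
* B: gain 100; one loss of −1250 at position 9;
* C: gain 50; five losses of −50 (positions 3, 5, 7, 9, 10) — C's losing
  cards therefore net exactly 0;
* D: gain 50; one loss of −250 at position 10.

The classic task varies card order between cycles; only the per-cycle net
sums, loss counts and fixed gain amounts are behaviorally load-bearing for
this model, so those invariants are validated on every load (and are all
the tests assert), while the within-cycle ordering is an editable detail
of the data file. Each deck's stack position advances only when that deck
is picked, and positions wrap past card 40 — deck depletion is not
modelled.

## The model

Net payoff x is valued with the prospect-utility function

    u(x) = |x|^α           if x ≥ 0
    u(x) = −λ·|x|^α        if x < 0

with shape α ∈ [0, 1] and loss aversion λ ∈ [1, 2.5]. We take 0⁰ := 1
(IEEE pow), so at α = 0 the utility is a step function: +1 for any
non-negative net, −λ for any loss. Note the deliberate consequence for
deck C: its net-zero losing cards fall in the gain branch and are valued
+1 at α = 0. The α = 0 agent is a pure gain-stay / loss-shift strategist.

Deck expectancies E_j start at 0 and are updated by one of two rules with
rate A ∈ [0, 1]:

* **DEL** (delta rule): the chosen deck moves toward the utility,
  E_j ← E_j + A·(u − E_j); other decks are untouched. Expectancies stay
  inside the convex hull of 0 and the utilities seen so far.
* **DRI** (decay reinforcement): every deck decays, E_j ← A·E_j, and the
  chosen deck adds u.

Choices follow a ratio-of-strength softmax,
Pr_j = exp(θ·E_j) / Σ_k exp(θ·E_k), computed with max-subtraction so large
expectancies cannot overflow. The response-consistency parameter of older
expectancy-valence models is removed; the three free modulators are α, λ
and A. θ is fixed at 1.0 by default (the minimal reading of "choice
responds directly to α, λ, A") but is exposed on every entry point, since
a trial-indexed sensitivity is a known variant in this model family.
Because E(0) = 0, the first trial is always at the four-deck chance level
(0.25 each) under both engines.

## Prediction engines

* **General simulation**: the model plays the game — sample a deck from
  the current probabilities, deal from that deck's own stack, value,
  update, repeat. All randomness is pre-drawn choice uniforms, one per
  trial, consumed by inverse-CDF sampling; a game is fully determined by
  its seed.
* **One-step-ahead**: the model replays observed records and reports, for
  each trial, the probabilities it held before that trial. Deterministic.

Prediction matrices are pre-choice by construction, which is what makes
them comparable with the observed choice at the same trial index.

## Fitting

The benchmark is the trials × 4 matrix of cross-subject choice
proportions. Fit is the mean squared deviation (MSD) over all trials and
decks between a model's prediction matrix and the benchmark; likelihood
products (G²-style scores) are intentionally not offered because
successive choices are not independent. For the stochastic engine the
scored prediction is the *mean* trajectory over `n_reps` repeated games —
a mean prediction against a mean benchmark — not an average of per-run
MSDs.

The search is exhaustive over the 11 × 16 × 11 lattice (α, A: 0 to 1 by
0.1; λ: 1.0 to 2.5 by 0.1), 1936 points. Ranking ties are broken
lexicographically by (α, λ, A) so results are reproducible. The
top-fraction analysis takes the `ceil(fraction·N)` lowest-MSD points
(10% of 1936 → 194) and tabulates one parameter's value frequencies —
the diagnostic separating parameters that steer the fit (α) from ones
that barely matter once α ≈ 0 (λ, and to a lesser degree A).

### Seeding and common random numbers

Every stochastic entry point takes one root seed. Repetition r of an
averaged simulation runs on the r-th spawned child seed, so any single
repetition is reproducible in isolation; cohort subjects are seeded the
same way. Within a grid search the *same* per-repetition draws are reused
at every grid point (common random numbers): MSD differences between
neighbouring points then reflect the parameters rather than independent
sampling noise, which sharpens the argmin without biasing any individual
point's score.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: 145
subjects × 100 trials, each subject an independent game played by the
simplified model at its optimized constants (α = 0, λ = 1.3, A = 0.1,
θ = 1). This choice makes the generator double as ground truth for
parameter recovery. Optional per-subject parameter jitter (uniform within
a configurable radius, off by default) adds between-subject heterogeneity;
the reference model describes only the group mean.

What the generator does *not* emulate — and therefore what passing tests
cannot show about real data: real cohorts are heterogeneous mixtures of
strategies, show a late decline in deck-B selection that no
fixed-parameter agent of this family reproduces, and contain
response-time and perseveration structure outside the model. Recovery
results certify the pipeline (generate → aggregate → search), not the
claim that human cohorts are this agent.

## The recovery experiment and its error budget

The headline experiment regenerates the default cohort, aggregates it,
and grid-searches it back with the DEL rule. Two noise sources compete
with the parameter signal: the benchmark's own sampling noise (binomial
with n = 145, per-entry s.e. ≈ 0.036 near p = 0.25) and the scorer's
Monte-Carlo error in each point's mean trajectory. The repetition count
for this experiment is set to 400 so the scorer's error sits well below
the benchmark's; at that precision α and A recover exactly (or within one
grid step) on every cohort realization we have run, while λ lands within
one 0.1 grid step on only about 70–75% of realizations — the same rate as
at 100 repetitions, and raising repetitions to 1600 does not move the
outlying cohorts. The λ scatter is therefore not an estimator artifact
but genuine weak identifiability: with α ≈ 0, λ expresses itself only on
loss trials, which are a minority of picks, so a 145-subject benchmark
carries limited information about it and its sampling noise can flip the
argmin between adjacent λ values. Single-cohort λ estimates should be
treated as ±0.2; consensus across replicate cohorts (as the reproduction
script reports) is stable at 1.3. This is the same hierarchy of parameter
influence (α ≫ λ, A) the top-fraction analysis shows.

Elsewhere the library default stays at `n_reps = 100`, a reasonable
accuracy/cost point for interactive fitting.

## Numerical and degenerate-input conventions

* Softmax via max-subtraction; non-finite expectancies raise rather than
  propagate NaNs.
* 0⁰ := 1 in the utility (see above); utilities are exact at α = 1
  (linear) and α = 0 (step).
* Grid values are rounded to 10 decimals at construction so 0.30000000004
  artifacts cannot leak into reported optima.
* Empty cohorts, zero-trial requests, gapped trial indices, ragged
  cohorts, unknown deck labels and malformed CSVs all raise `ValueError`
  (schedules: `ScheduleError`) at the boundary.
* MSD of an empty grid, fractions outside (0, 1], and mismatched matrix
  shapes are rejected.

## Problem sizes used in the shipped checks

Structural and arithmetic checks run on miniature inputs (tens of trials,
a handful of subjects). The recovery-style checks use the full study
shape — 145 × 100 cohorts, the complete 1936-point lattice — with 400
repetitions per grid point in the headline experiment and 100 where only
orderings (DEL vs DRI) or qualitative patterns (deck A least chosen) are
at stake. A full 400-rep search takes on the order of half a minute on
one CPU core.

## Known limitations

* The one-step-ahead engine scores a cohort by averaging per-subject
  prediction matrices; per-subject (hierarchical) fitting is out of scope.
* No likelihood-based or gradient optimization; the lattice is the search
  space, so reported optima inherit its 0.1 resolution.
* The schedule models the classic four-deck economy only; variants with
  different cycle nets or loss frequencies are loadable but the loader's
  invariants must then be relaxed by editing the data file *and* the
  validator's constants.
* Descriptive summaries only; inferential statistics on cohorts are left
  to general-purpose stats packages.
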