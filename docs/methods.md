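# Methods

This note records the model underlying the package, the operational
choices made where the index definition is open to interpretation, what
the synthetic-data generator does and does not emulate, and the numerical
conventions. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The index model

The DHSI treats an episode's health state as a function of 29 binary
indicators, aggregated in two stages.

**Lexicographic weighting.** Each parameter belongs to an ordered class
(exponent k of a base-6 coefficient, k = 0…10) and carries an intra-class
value code v ∈ {1, 2, 3}; its weight is v·6^k. Base 6 is the maximum class
size, and 6·1 > 3 guarantees that any single parameter of class k+1
outweighs any single parameter of class k. The scheme is *pairwise*
lexicographic only: it does not guarantee dominance over **sums** of lower
classes (e.g. the weight-6⁴ parameter Y9, 1296, is outweighed by the four
weight-2·6³ parameters combined, 1728). The package reproduces the
published weights verbatim and exposes `dominance_report()` so users can
see exactly where sum-dominance fails, rather than silently altering the
scheme. Alternative weightings for sensitivity analyses load from a YAML
file (`WeightScheme.from_file`).

**Rank merging and normalization.** Positive and negative pre-scores are
integer sums (exact; the largest value, 3·6¹⁰, is far below 2⁵³). Episodes
are ranked ascending on the positive and descending on the negative
pre-score with midrank (average) tie handling — ties are inevitable at
scale with binary inputs, and midranks keep the mean rank symmetric. The
mean rank is rescaled linearly to [0, 100]. When every mean rank is equal
no scale exists; `normalize` raises rather than fabricating a constant.
Mean ranks and index values are kept as unrounded floats.

## Episode selection conventions

The selection criteria mix month- and day-denominated windows; fixed
conversions are used throughout for internal consistency with the
day-denominated parameter definitions: 6 months = 183 d, 9 months = 275 d,
5 months = 152 d, 1 month = 31 d, 3 months = 92 d.

- *Incident depression diagnosis*: no depression diagnosis in the 183 days
  before the qualifying diagnosis (the same washout length as for the AD
  prescription, reused for symmetry; the definition itself names no
  window).
- *Monotherapy*: exactly one distinct AD molecule prescribed on the index
  day. Later additional molecules are treatment-pattern parameters
  (switch/combination), not exclusions.
- *Multiple episodes per patient*: the 183-day AD washout is the sole
  overlap rule; any later prescription date satisfying it anew can anchor
  a further episode. A consequence worth knowing: inserting an AD
  prescription shortly before a formerly qualifying index date does not
  simply delete the episode — the earlier prescription may itself qualify
  and anchor the episode at the earlier date.
- *Age*: from the year-of-birth record with a July-1 convention (the data
  model carries only birth year).
- *Data coverage*: from each patient's first and last recorded event; the
  post-index requirement is waived when death occurs within 275 days.

## Parameter detection conventions

- "At least 2 consecutive visits" (X1/X2) means adjacent visits in the
  follow-up visit sequence; operationally, ≥ 2 visit dates strictly after
  the last disqualifying prescription in follow-up (which implies a clean
  adjacent pair and no later prescription). "Psychiatric co-prescription"
  is the union of the psychotropic non-AD event types (psychiatric,
  hypnotic, antipsychotic/lithium prescriptions).
- Inter-visit gap statistics need ≥ 3 visits (≥ 2 gaps) in each period;
  otherwise X3/Y14 are 0. When the baseline gap SD is exactly 0 the
  comparison degenerates to "≥ mean", which would set both X3 and Y14 for
  an unchanged mean; a strict change is required in that case so the pair
  stays mutually exclusive.
- All "lower/higher number (no threshold)" comparisons are strict;
  equality is neither lower nor higher.
- An AD *stop* is the last prescription date plus its coverage days. For
  relapse detection (Y13), stops are the right endpoints of merged
  coverage intervals, so an unbroken refill chain has a single stop.
- Switch (Y7): the first different-molecule AD prescription must fall in
  [stop − 31 d, stop + 183 d] and inside follow-up. Combination (Y11): a
  different AD starting at least 31 d before the initial stop, with
  coverage overlapping both the initial treatment span and the follow-up
  window. Augmentation (Y12): same arithmetic with antipsychotic/lithium
  against the end of all AD treatment.
- Dose comparison (X10/Y15): coverage-weighted mean daily dose; the
  reference is the last 31 days of baseline; defined only when no other
  AD molecule appears in the observation span.
- X9 (pregnancy) is read over the full observation period (baseline start
  to follow-up end), as its definition states, unlike the other incident
  flags which read follow-up.
- Death truncates the follow-up window for period summaries (counts, gap
  and dose statistics); incident event flags read the recorded data as-is
  (no events exist after death in consistent data).
- Undefined comparisons (too few visits, no dose data, modified molecule)
  yield 0 — absence of evidence of change is treated as no change.

## Model distillation

The initial model is OLS of the normalized score on the 29 main effects
(statsmodels). The interaction tree splits each node on the parameter
maximizing |mean(y|x=1) − mean(y|x=0)| among splits leaving both children
with ≥ `min_node_size` (default 50) episodes — ties broken by larger SSE
reduction, then parameter order — and accepts a split only when it raises
the overall tree R² (1 − SSE over leaves / SST at root) by more than
`delta_r2` (default 0.01). The unweighted mean-difference criterion is the
literal reading of "largest difference in the average score"; the SSE
tie-break doubles as a size-aware fallback. Candidate interactions are all
ancestor–descendant splitter pairs on root-to-leaf paths
(`mode="ancestor"`, the default; `mode="parent"` restricts to adjacent
pairs) — ancestor pairs subsume the parent-child reading. Product columns
that are exactly linearly dependent on the design (singular-value
tolerance 1e-8, greedy column scan) are dropped and logged; which columns
fall is data-dependent, never hard-coded. Predictions are clamped to
[0, 100] and clamping events counted: out-of-range predictions are
possible for covariate patterns outside the learning sample and silent
extrapolation would be worse.

Zero-variance response: R² is defined as 0 and all slopes as 0.

## Hold-out evaluation

`|test| = round(0.1·n)` by uniform draw without replacement. The test
sample is ranked and normalized **within itself**, with no reference to
the learning sample; its scores are therefore scale-relative to the test
sample — this is deliberate and matches an evaluation that must not leak
learning-sample information, but it means test residuals mix model error
with re-normalization error. The test residual SE is √(Σr²/(n−1)) about
zero — a dispersion-about-perfect-agreement convention; no model degrees
of freedom are subtracted out of sample. Quartile boundaries are the
empirical 25/50/75 percentiles with ties to the lower quartile, keeping
counts as balanced as discrete scores allow. The remission proxy scans
merged AD coverage within follow-up for an uncovered run of ≥ 45 days,
counting gaps abutting the window edges; the 45-day bound is inclusive.

## The synthetic generator

The generator exists because the data the index was designed for is not
redistributable. It emulates exactly what the pipeline reads and no more:

- **Parameter matrices** (`generate_parameter_matrix`): a latent severity
  scalar s ~ Normal(0, 1) per episode; parameter j is
  Bernoulli(clamp(p_j + λ_j·s)) with λ < 0 for improvement and λ > 0 for
  worsening parameters; remission is Bernoulli(clamp(0.55 − 0.20·s)).
  A single latent factor is the minimal structure making both the
  parameter correlations and the remission-by-quartile gradient emergent
  rather than hard-coded. Default prevalences keep catastrophic events
  rare (death 0.005, ECT 0.005) and treatment-pattern events common
  (switch 0.12, relapse 0.15); they are round plausible values for a
  treated-depression cohort, not calibrated to any published figures.
- **Event streams** (`generate_event_stream`): registration spans
  bracketing a 2006–2012 study window, Poisson GP visits (default 1 per
  30 days), AD initiation with monthly 30-day prescriptions whose
  persistence, switching, co-medication and adverse events load on the
  patient's severity, plus background somatic care, a configurable
  bipolar/schizophrenia fraction and rare deaths. Internal-consistency
  guarantees: no events after death; every prescription date is a visit
  date.

What it does **not** emulate: realistic national prescribing patterns,
coding-dictionary structure (events are typed categories, not Read/BNF
codes), practice-level data-quality flags, free text, seasonality, or
informative censoring beyond death. Passing tests therefore demonstrate
that the pipeline's logic is correct and its expected qualitative
behaviour (model improvement from planted interactions, monotone
remission gradient) emerges under the stated generative assumptions — not
that the index is valid on any particular real database.

`simulate_scored_dataset` plants known pairwise interactions into a linear
score over a generated matrix (default noise SD 5 on a 0–100 scale) for
testing interaction discovery against ground truth.

## Problem sizes and determinism

Default analysis sizes: 20,000 episodes for quartile summaries, 5,000
(90/10 split) for hold-out model comparison, a few hundred patients for
full event-stream runs — large enough for stable directions at interactive
runtimes. Every stochastic component takes an explicit integer seed
(numpy `default_rng`); identical seed and configuration give bit-identical
outputs, including CSV round-trips.

## Known limitations

- The event-level detectors assume one prescription row per dispensing
  with a daily dose and coverage; free-text or quantity-based dosing is
  out of scope.
- Episode selection derives data coverage from observed events, which
  undercounts coverage for patients with sparse visit histories.
- With small samples (n below a few hundred) rare parameters are constant
  columns; they are dropped from the regression as collinear with the
  intercept and reported in `dropped_terms`, so their coefficients are 0
  rather than estimated.
- The ranking step is O(n log n) but pre-score computation iterates rows
  in Python; matrices of millions of episodes would want vectorization.
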