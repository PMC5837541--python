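# Methods

## Sequence model and pre-processing

A recording is `n_days` × `epochs_per_day` one-minute epochs of integer
activity counts, indexed from recording start; day boundaries are fixed
1440-epoch blocks from that start, not calendar midnight, because devices
in the target design start recording at a programmed clock time and the
analysis is indexed by recording sequence. Recordings shorter than the
nominal length are rejected by default; `pad_trailing` (or
`pad_partial=True` in the readers) instead appends pre-masked epochs, for
cohorts where trailing partial days should be retained.

Non-wear is any maximal run of zero counts of length strictly greater
than 60 epochs ("greater than one hour" read literally: a run of exactly
60 zeros is wear). Zeros that survive masking are ordinary sedentary
time — only long runs are evidence the device was off. Detection only adds
to the missing mask and depends on the counts alone, so it is idempotent.

Cut-points (counts/min): S ≤ 100 < L ≤ 2019 < M ≤ 5998 < V. These are the
conventional uni-axial waist-worn thresholds for children and are fully
configurable; categorization is a total function on non-negative counts.

Validity: a day is valid with ≥ 480 worn epochs (8 h); a participant is
valid with ≥ 3 valid days and wear-time mean ≤ 1500 counts/min. The
1500-cpm rule is evaluated on the wear-time mean (the same quantity as
mCPM), which we consider the only self-consistent reading; a
whole-recording mean would depend on the amount of non-wear. sdCPM uses
the sample (n−1) standard deviation; with a single worn epoch it is
reported as 0.

## Bigram features

Bigram counting sums over every adjacent index pair of the full multi-day
sequence (the literal i = 1…n−1 summation), so pairs spanning a day
boundary inside the continuous recording are included. Pairs touching a
masked epoch are excluded entirely: a bigram asserts adjacency in worn
time, and neither side of a wear/non-wear junction can support that claim.
This exclusion rule is a reasoned design choice, not a documented
equivalence with any particular historical implementation.

The primary analysis divides by D = total recorded days regardless of
wear. The sensitivity mode (`day_policy="valid_days_only"`) masks whole
days below the 8-h wear threshold — dropping pairs that touch them while
keeping pairs across the boundary of two adjacent retained days — and
divides by the number of valid days.

For same-state u-bigrams the two indicator clauses of the pooling formula
coincide, so each AA pair counts once: `bu[AA] = b(A,A)`, never doubled.

`bigram_minute_span` reports the distinct epochs covered by a bigram's
occurrences; it exists because overlapping pairs make frequency and time
non-equivalent (two SS pairs can cover three or four minutes).

## Swap regressions

All models are ordinary least squares with an intercept. The remainder
terms use the nominal daily budgets — r = nd − (comparison + baseline
minutes), rb = (nd − 1) − comparison − baseline frequency — even when
non-wear reduces the observed budget, because the contrast is defined
against the fixed day length; `use_observed_pairs=True` substitutes each
participant's observed valid pairs per day for auditing. Confidence
intervals are 95% t-intervals on residual degrees of freedom (at cohort
sizes in the thousands these are indistinguishable from normal
intervals). Scaling: `per_10` multiplies β1 (and its CI) by 10; `per_sd`
by the sample SD of the baseline feature among the analysis rows, stored
in `sd_of_baseline`. mCPM effects are reported per 100 counts/min, sdCPM
effects per sample SD of sdCPM.

Exchanging baseline and comparison replaces the design column x_c by
x_b = const − x_c − r, a linear reparametrization of the same column
space, so the swapped estimate is exactly −β1 with identical standard
error; the test suite asserts this to 1e-10 relative.

Complete-case analysis is applied per model and `n_used` reported.
Categorical covariates enter as the numeric codes supplied in the
phenotype table (ordinal treatment); dummy-code them upstream if
preferred. Rank deficiency raises a collinearity error naming the
offending columns (identified by pivoted QR); a zero-variance model
feature raises a degenerate-feature error. No multiple-testing correction
is applied across the contrast grid — intervals are per-contrast, as is
conventional for this descriptive design — and grids report one
orientation per unordered pair since the other is its exact negation.
Adjustment sets model 3 and model 4 (state durations, mCPM) are defined
for frequency swaps only; transfer-of-time models accept model 1 and 2.

## Synthetic cohort generator

The generator exists to make every pipeline stage testable with known
truth; first-order Markov paths were chosen precisely because their
stationary pair probabilities π_A·P[A→B] give a closed-form oracle for
expected bigram frequencies.

Defaults, and why:

- 7 days × 1440 epochs, 500 participants: the nominal recording design.
- Transition matrix: back-derived from the median daily bigram counts of
  a population child cohort (sticky S and L, M entered mainly from L,
  V rare and brief), then row-normalized. Stationary durations are
  roughly 680/645/107/5 min/day in S/L/M/V.
- Emissions: uniform within each state's cut-point band, vigorous capped
  at 10 000 counts/min to keep mCPM realistic (~850) and below the
  1500-cpm validity cap unless exclusion paths are deliberately
  exercised. Ranges crossing a cut-point are a config error, which is
  what guarantees the emit→categorize round trip.
- Non-wear: Poisson(0.5/day) runs, lengths uniform on 61–480 epochs,
  written as zeros at uniform positions; overlaps merge naturally. This
  is the simplest mechanism that exercises the >60-zero rule.
- Outcome: intercept 21.5 with default coefficients [MV] −0.13 per daily
  pair and Md −0.02 per min/day, noise SD 3.3 — centring the outcome near
  19 with dispersion and effect magnitudes typical of child BMI analyses.

Confounder draws use a dedicated seed stream shared by
`simulate_sequences` and `simulate_outcomes`, so the values that select a
participant's transition matrix are identical to the values entering the
outcome; all randomness derives from the single config seed via named
`SeedSequence` substreams.

What the generator does **not** emulate: diurnal/circadian profiles,
weekday-weekend structure, semi-Markov (heavy-tailed) bout durations,
device-specific count noise, or informative non-wear. Passing tests
therefore demonstrate correctness of the arithmetic and calibration of
the inference under the stated generative model, not robustness to the
richer dependence structure of real accelerometry.

## Problem sizes used in validation

The calibration experiment fits the [SS]→[MV] u-bigram swap on 200
independent cohorts of 1000 participants each (full 7 × 1440 sequences,
default non-wear), with a configured direct effect of −0.5 per daily pair
chosen so that the Monte-Carlo error of the 200-replicate mean is well
inside a ±5% bias band; empirical 95% CI coverage is required in
[92%, 98%]. The Markov-oracle check uses a uniform-row chain with ~10⁵
observed pairs and a 3-SE binomial band (uniform rows make adjacent pairs
effectively independent, so the binomial SE is valid). Conservation and
symmetry properties are checked on 1000 random masked sequences.

## Known limitations

- Bigram frequencies enter the regressions as fixed covariates; their
  sampling error over a finite week is ignored, so CIs are, if anything,
  slightly anti-conservative.
- Only 2-grams are implemented; higher-order n-grams lose power rapidly
  as occurrences thin out, and bout-length statistics are out of scope.
- The long-format counts CSV is the only ingestion path; proprietary
  device formats and sub-minute raw accelerometry are not parsed.
- Ordinal coding of categorical confounders is the default; the package
  does not construct dummy variables itself.
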