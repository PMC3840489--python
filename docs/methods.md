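# Methods

This note documents the models, parameter choices and numerical
conventions behind `mirpain`, and what the synthetic-data tests do and do
not establish about real data.

## The dysregulation screen

The screen operates per timepoint on quantile-normalized, linear-scale
intensities. Quantile normalization replaces each array's sorted value
vector with the across-array mean of sorted vectors, preserving
within-array ranks; ties within an array receive the mean of the
reference values their rank span covers, which makes the transform
deterministic and idempotent. No log transform is applied before the
selection rule: the criterion and the fold change are both homogeneous of
degree one in intensity, so all pass/fail decisions are invariant to
global intensity scaling.

A miRNA is selected when |m_T − m_S| ≥ k·(s_T + s_S) with k = 5 and
FC = m_T/m_S ≥ 2.5 or ≤ 1/2.5. Conventions:

- **SD**: sample SD (n − 1 denominator) by default; population SD is
  available (`sd_mode`). With n = 3 replicates per group the choice
  shifts both SDs by the same factor, so it only rescales the effective k.
- **Inclusive boundaries** for both inequalities ("at least" semantics).
  The comparisons carry a 10⁻¹² relative tolerance so that decisions at
  an exact boundary do not flip under floating-point rescaling.
- **Downregulation** is reported as FC < 1 with the threshold applied to
  the reciprocal; no signed fold changes.
- **Non-positive group means** make a fold change undefined; such miRNAs
  are flagged unevaluable and excluded from selection, never dropped
  silently or crashed on.
- A looser fold-change-only count at 2.0 is reported alongside the
  selection for context; it applies no consistency requirement.

`implied_t_bound(k, n)` gives the worst case, over all SD configurations
on the criterion boundary, of the pooled-variance two-sample t-test p.
On the boundary |m_T − m_S| = k(s_T + s_S), the statistic
t = k(s_T + s_S)/√((s_S² + s_T²)/n) is minimized as one SD tends to zero
(the ratio (a+b)/√(a²+b²) attains its minimum 1 at the axes), giving
t_min = k√n with 2n − 2 degrees of freedom. For k = 5, n = 3 this is
p ≈ 9.78 × 10⁻⁴; equal SDs give the larger t = k√(2n) and hence a smaller
p. The test suite confirms the supremum by grid search.

## ΔΔCт quantification

Technical replicates are averaged per (sample, assay) first; a QC flag
(default bound 0.5 cycles replicate SD) marks noisy wells without
excluding them, since the source protocol states no outlier rule. ΔΔCт
is computed from per-sample ΔCт means, respecting biological-replicate
structure (with balanced data this equals the pooled-means computation).
Amplification efficiency is fixed at perfect doubling — fold change
2^(−ΔΔCт) — with no efficiency calibration. Undetermined Cts are treated
as missing and counted, never imputed at a ceiling. Fold changes are
invariant to any global Ct shift, and swapping treatment/control labels
inverts them exactly.

## Target consensus and response filter

The consensus rule counts **distinct** algorithms per (miRNA, gene);
duplicate records collapse with a warning. The 14 external prediction
algorithms are never executed — availability and versioning of those
tools is outside reproducibility scope — their outputs are consumed as
long-format tables.

Housekeeping normalization divides each sample's counts by the geometric
mean of that sample's flagged housekeeping genes, the standard
multi-reference convention; it is exactly invariant to per-sample
scaling. "At least 50% up-regulation" is interpreted as the ratio of
condition means of normalized counts ≥ 1.5, inclusive (with the same
10⁻¹² boundary tolerance as the screen).

The reciprocal-regulation score counts shared timepoints where the miRNA
and candidate log2 fold changes are both nonzero with opposite signs; a
zero log fold change is direction-less and never concordant. The default
flag threshold, ceil(shared/2) + 1 concordant timepoints, is an artifact
decision (a strict majority plus one), and is a parameter.

## von Frey reductions

Withdrawal frequency is 100 × withdrawals/trials (five trials per
filament by default, so per-animal frequencies are multiples of 20%).
Thresholds interpolate **linearly in log10 force** between the first
adjacent filament pair bracketing the quantile: filament sets are
log-spaced and psychometric functions are conventionally modeled on log
stimulus. The first-crossing rule makes non-monotone curves
deterministic and order-independent. Censoring: quantile already reached
at the weakest filament → left-censored at that filament; never reached →
right-censored at the strongest; flags are always emitted, and censored
animals enter group means at their censoring bound with the censored
fraction reported. The response quantile (50% default, 80% supported) is
a parameter throughout.

AUC is the trapezoidal integral of frequency over log10 force across the
full filament range (units: % × log10-gram; maximum 100·log10(50) ≈
169.90 on the default 0.02–1.0 g set). A linear-force abscissa is
available (`--auc-scale linear`) for sensitivity analysis; the scale used
is recorded in output metadata.

Group statistics reduce per animal first, then average over mice with
SEM (undefined, reported missing, for a single animal), matching how
behavioural cohorts are reported.

## Synthetic data: what it emulates and what it does not

All generators are deterministic given a seed, and every planted effect
is emitted in a separate ground-truth JSON, never embedded in the data.

- **Arrays**: per-miRNA baselines are log-normal (log2 mean 10, log2 SD
  2.0, i.e. intensities spanning roughly 2.5 orders of magnitude, as on
  real expression arrays); within-group noise is multiplicative
  log-normal with a given linear-scale CV, so intensities stay positive
  and right-skewed, and zero CV is exactly noiseless. Planted miRNAs get
  tumour-group expected means multiplied (up) or divided (down) by the
  planted fold change. Effects are planted only within the central 90%
  of the baseline distribution: quantile normalization cannot represent
  a fold change of a probe at the distribution extremes (there is no
  headroom in the shared reference distribution), just as saturated or
  floor-level probes on a real array cannot show fold changes. The
  default conditions (615 miRNAs, 26 up + 31 down at 3-fold, CV 5%,
  n = 3 per group) are the study conditions the screen is benchmarked
  under; with them the screen recovers the planted sets exactly at zero
  noise and with ≈ 0.99 sensitivity / 1.00 specificity over 20 seeds.
- **Ct tables**: reference assay Cт is group-independent; target Cт
  encodes the planted fold change as ΔΔCт = −log2(FC); noise is additive
  Gaussian in cycles.
- **Predictions**: planted genes are predicted by exactly their support
  count of algorithms (a seeded random subset); background genes are hit
  independently per algorithm at a configurable rate.
- **Counts**: "digital counts" are continuous non-negative values
  (expected value × multiplicative log-normal noise, not
  integer-rounded), so the zero-dispersion funnel recovers planted
  response ratios exactly; per-sample depth factors are drawn so that
  housekeeping normalization is actually exercised.
- **Behaviour**: withdrawal counts are binomial (n = 5) draws from a
  logistic psychometric in log10 force with floor/ceiling, slope 4 per
  log10 unit (a 10–90% width of about one log unit). The tumour group's
  threshold follows a configured day-by-day trajectory (default 0.6 g →
  0.05 g over days 0–8); sham stays at baseline. With these settings the
  per-animal first-crossing estimator tracks the planted trajectory to
  within ±10% in the mean over large cohorts; the residual positive bias
  comes from frequency quantization and censoring at the filament-grid
  edges.

The generators deliberately omit probe-level array artefacts (background,
bead-level variance), sequence-based target simulation, and
count-specific mean–variance laws. Passing the planted-recovery tests
therefore demonstrates correctness of the *computational* pipeline under
its stated noise models — not that the screen's operating characteristics
transfer to any particular real array platform or tissue.

## Problem sizes and determinism

Tests and the acceptance script use the full default screen size
(615 miRNAs × 6 arrays; 20 seeds for stochastic recovery), exhaustive
enumeration of all 6⁵ quantized response curves against a dense-grid
threshold oracle, 100-seed Monte-Carlo for ΔΔCт unbiasedness, and
500–2000-mouse cohorts for behavioural recovery — sizes at which every
check runs in seconds. End-to-end pipeline runs with a fixed seed are
byte-identical, including metadata headers; the run manifest lists every
artifact exactly once.

## Known limitations

- The screen's operating characteristics depend on the fraction of
  truly changed miRNAs: quantile normalization compresses planted fold
  changes when planted rows dominate the value distribution (noticeable
  above ~10% of rows), which is a property of the method, not of this
  implementation.
- The worst-case t-bound assumes the equal-variance two-sample t-test;
  it is a bound on the boundary of the selection region, not a per-miRNA
  p-value, and no multiplicity correction is attached to it.
- Threshold interpolation between filaments is a convention; two
  conventional choices (log-linear vs linear force) differ most between
  widely spaced filaments, which is why the AUC scale is recorded in
  output metadata.
- Inferential statistics on the reduced behavioural tables
  (repeated-measures ANOVA, post hoc tests) are out of scope; the
  pipeline emits tidy per-animal tables consumable by any statistics
  package.
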