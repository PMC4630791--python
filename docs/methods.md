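# Methods

## Scoring model

Norm tables are built per subtest and age bin by ranking the observed
raw scores (mid-rank for ties), converting rank *r* among *n* to the
percentile (r − 0.5)/n, and mapping through the standard normal
quantile onto the 100/15 scale.  The (r − 0.5)/n plotting position is
the package default because it is exactly symmetric — the scaled-score
sample mean is 100 to machine precision for distinct values — and never
produces infinite quantiles at the extremes; r/(n + 1) is available as
an option.  The sample SD converges to 15 from below (≈ 14.9998 at
n = 10,001).  Ties share a mid-rank and therefore a scaled score.
Trail Making A and B are ranked on negated raw scores (completion time,
lower is better); the other six subtests are counts, higher is better.

Age bins are half-open [lower, upper) on continuous age: 13–19, twelve
5-year bins, and 80–89 (upper edge 90).  Ages outside [13, 90) are
outside the normative range and rejected.  Bins need at least two
subjects; an empty or singleton bin is an error naming the bin, rather
than a silently widened neighbor.

Scoring a new individual uses a step-function lookup: an unseen raw
value takes the scaled score of the nearest observed raw value on the
*worse*-performance side, clamping beyond the observed range.  This
floors rather than interpolates so performance not demonstrated in the
norming data is never credited, and it preserves monotonicity exactly.
The Grand Index applies the same transformation to the sum of the
eight scaled scores over the norming cohort; the resulting sum → index
step table is serialized alongside the subtest tables, so new
individuals are scored against fixed norms.  Re-scoring the norming
cohort through its own tables reproduces every score bit-for-bit
(exact raw values hit exact table entries).

## Cohort simulator

The generator emulates the statistical anatomy the validation pipeline
needs, not the content of any subtest.

**Latent structure.** Standardized subtest scores follow the
four-factor model z = Λf + √ψ·ε with the published varimax loading
matrix (blank cells taken as 0, an approximation documented below) and
ψ = 1 − Σλ².  The implied Forward:Reverse Memory Span correlation is
0.513, the largest off-diagonal entry, matching the published ordering.

**Demographics.** Ages come from a two-component uniform mixture on
[13, 45) and [45, 89] weighted to mean 46.3; recorded gender is
F/M/undisclosed at 53.3/40.1/6.6%; education years are drawn within
the published attainment categories (8–12, 13–16, 17–20 years at
14.4/45.4/30.2%, 9.9% undisclosed).  Undisclosed subjects still carry
latent values that drive their scores; only the recorded column is
masked.  A linear predictor with the published regression's
coefficient pattern (female, education, age, and the three pairwise
interactions) is standardized against a large fixed-seed calibration
draw and added to every subtest's standardized score with weight √v.
The variance share v ≈ 0.177 is solved in closed form so the
demographic regression on the non-age-normed sum score explains R² =
0.361, the published figure; with that single scale fixed, the implied
sum-score coefficients keep the published signs and relative
magnitudes at about 77% of the printed absolute values (the printed
outcome scale is not exactly reproducible from the printed R², and the
package treats its own implied coefficients as the recovery targets).
`SimulationConfig.expected_sum_coefficients()` exposes them.

**Retest scores.** Session 2 is generated per subtest as
t₂ = ρ*·t₁ + √(1 − ρ*²)·ε.  ρ* is solved numerically so the
*observable* correlation of age-normed scaled scores equals the
published per-subtest target, accounting for two attenuations: (a)
age-binned norming removes the between-bin share of the demographic
component from both sessions while session 2 retains only ρ* of it —
handled by a bin-weighted closed form over the within-bin demographic
variances; (b) rounded raw-score links and the step-table lookup tie
nearby latent values — handled by a per-subtest attenuation factor
estimated once from a fixed-seed replay of the exact observation chain
at the bin size the configured cohort will produce.  A small residual
attenuation (~0.01 in r, from the interaction of the rank transform
with the non-normal demographic mixture) remains and is visible as a
slight downward tendency in recovery checks; it sits well inside the
3-Monte-Carlo-SE tolerance the tests use.  The practice effect is
injected as a mean shift only (+1.1 Grand Index points, converted to
the latent scale through the model-implied within-bin sum SD); the
published SD of retest change emerges from the retest noise and is not
a separate noise source — injecting it would destroy the calibrated
reliabilities.

**Clinical groups.** Self-report MCI and AD subjects are 50+ (truncated
normal ages at the published means/SDs) and receive per-subtest latent
shifts proportional to the published deficit profile, rescaled so the
model-implied age-normed Grand Index gap equals the configured target
(11.0 / 16.1 points).  The conversion uses the within-bin sum SD
weighted by the *group's* age distribution, because the age
interactions make older bins demographically more homogeneous.

**Engagement.** Inter-test interval, unique days played, and games
played follow the published moments and ranges (truncated normals with
the location solved so the truncated mean matches the published mean;
games played is a moment-matched lognormal).  They are independent of
scores by default; `engagement_noise` κ > 0 multiplies session-2 noise
variance by 1 + κ·games/mean(games) to exercise the two-stage variance
model.

**Raw-score links.** Counts are affine-plus-rounding with floors (and
a 17-item ceiling for Progressive Matrices); times are log-scale affine
giving right-skewed seconds.  The links are plumbing: the norming
transform is rank-based, so any strictly monotone link yields the same
scaled scores up to tie granularity.  No published raw-score
distributions exist to calibrate them against.

**What the simulator does not emulate.** Raw-score distributions
beyond shape; training-induced gains; correlated session-specific
noise across subtests (see limitations); non-linear age trajectories
(the injected age effect is linear-with-interactions, so peak-age
curvature in the source data is not reproduced); race/ethnicity and
other demographics outside age, gender, education.

## Reliability machinery

Pearson r with the Fisher-z analytic interval
tanh(atanh r ± z*/√(n−3)); simulated coverage at ρ = 0.8, n = 100 is
≈ 0.95.  The bootstrap resamples whole pairs with replacement (10,000
iterations by default), reports median/IQR/2.5–97.5 percentile
interval, and drops degenerate resamples with a logged count.
Grouped estimates support explicit labels, mean ± 0.5/1.5 SD interval
bins (edges rounded to integer days, an edge day starting its bin, so
a 78.8/19.86 ITI reproduces the 29–68 / 69–88 / 89–108 / 109–235
ranges), and right-closed integer quartile cuts.  The engagement model
is two OLS stages — levels, then squared residuals on the engagement
counter — with conventional standard errors by default and HC3 as an
option.

## Factor analysis

The ML fit is the profile-likelihood algorithm: minimize the ML
discrepancy over log-uniquenesses with the analytic gradient
(L-BFGS-B, ψ floored at 0.005 with a Heywood flag), loadings recovered
from the eigen-decomposition of ψ^{-1/2}Rψ^{-1/2}.  This is
implemented in-package because the installed statsmodels ML fitter
fails to converge on exactly this model class; the implementation was
verified against R's `factanal`/`varimax` during development and
recovers the population solution to 4 decimals.  Varimax uses the SVD
iteration with Kaiser row normalization; columns are ordered by
explained variance and signed to non-negative column sums.  Fit
statistics: Bartlett-corrected χ² = (n − 1 − (2p+5)/6 − 2k/3)·F,
df = ((p−k)² − (p+k))/2, RMSEA = √(max(χ²−df, 0)/(df(n−1))) with the
noncentrality interval from inverting the noncentral-χ² CDF.

Parallel analysis compares eigenvalues of the *reduced* correlation
matrix — communalities from an iterated principal-axis solution on the
diagonal — against the same quantity on i.i.d. standard-normal
matrices of identical shape, retaining factors while the observed
eigenvalue exceeds the 95th-percentile reference (mean available).
This factor-solution flavor is the one that can resolve the weak
fourth factor (2.6% of variance): raw-SMC reduced eigenvalues put the
population's fourth eigenvalue below zero and can never retain it, and
the principal-component flavor retains at most two.

The 0.4/0.3 simple-structure screen takes "0.4 or above" as ≥ and "no
cross-loading of 0.3 or above" as second-largest |loading| < 0.3.

## Matching

Exact matching discretizes age and education to integer years
(truncation) and uses recorded gender; rows missing a key never match.
Each case consumes one uniformly-drawn eligible control without
replacement; unmatchable cases are dropped and counted, never
approximately matched.  Repeats shuffle case order and per-key
candidate order from independent spawned streams, so the spread of
per-run mean differences reflects genuine matching ambiguity and runs
are bit-reproducible given the seed.

## Numerical and testing choices

Stochastic tests are seeded and use 3-Monte-Carlo-SE tolerances (SE =
(1−r²)/√n for correlations) or ~3-SE windows sized from the relevant
sampling error; recovery checks compare against the package's own
model-implied targets, which is what the calibration promises.
Simulation sizes in the suite — 2,000–12,000 subjects for recovery
properties, 50,000 for factor-loading recovery, 1,000 reference
matrices and five seeds for parallel-analysis retention — were chosen
as the smallest sizes at which the targeted effects are resolvable at
those tolerances.

## Known limitations

- The battery-level Grand Index retest correlation emerges near 0.72,
  below the published 0.831, because the simulator draws retest noise
  independently per subtest.  Reproducing the published aggregate
  reliability would require correlated session-specific noise (a
  "good day" component); the per-subtest reliabilities, which are the
  calibrated quantities, hit their targets.
- Blank loading cells treated as 0 make the implied correlation matrix
  an approximation: its dendrogram does not separate the
  reasoning/coding trio from the trail-making pair the way the source
  data's did, and the varimax solution of the implied matrix differs
  from the printed loadings by up to 0.27 on the weak fourth factor.
  Structure tests therefore target the implied model's own population
  solution.
- Norm tables are discrete step functions; no smoothing or
  regression-based continuous norms are provided, by design.
- The matching keys' granularity (integer years) is a convention;
  category-level education matching is configurable but not the
  default.
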