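# Methods

## Reference-value models

Two model families cover the reference equations in practical use.

**LMS with an age spline.** The index distribution at (sex, age, height)
is summarised by skewness *L*, median *M* and coefficient of variation
*S*. The median is log-linear in height and age plus an age-spline
contribution; *S* is log-linear in age plus its own spline; *L* comes
directly from the age table. Spline values are interpolated **linearly**
in age between grid rows: published lookup tables use dense grids
(quarter-year to one-year) on which the curvature between rows is far
below any clinically meaningful difference, so higher-order
interpolation would add complexity without accuracy. Outside the
tabulated span the nearest row is used (constant extrapolation) and the
evaluation is flagged, not refused — see *Extrapolation* below.

The z-transform is computed as `expm1(L·ln(y/M))/(L·S)` and its inverse
as `M·exp(log1p(L·S·z)/L)`. These are algebraically identical to the
textbook forms `((y/M)^L − 1)/(L·S)` and `M(1 + L·S·z)^{1/L}` but remain
accurate as L → 0, where the naive forms lose all precision to
cancellation; the L = 0 logarithmic branch is exact. A property test
checks agreement with brute-force numeric inversion to 1e−7 over 1,000
random parameter draws.

**Linear with constant residual SD.** Classical regression references
predict the index from named polynomial terms in height and age
(optionally on the log scale) with a single residual SD, giving
z = (y − predicted)/SD. Such models are often *used* not through their
SD but through fixed percent-of-predicted cutoffs standing in for the
2.5th percentile (ratio < 88 %, FVC < 80 %, FEV1 < 80 % predicted);
when a model declares those cutoffs, a request for the 2.5th-percentile
LLN returns `cutoff/100 × predicted`, while every other percentile (and
all SD-band arithmetic) uses the residual-SD pathway. Height or age
values outside a classical model's original fitting ranges other than
the declared age range are not separately flagged, since those ranges
are typically unpublished.

## LLN policies and classification

An `LLNPolicy` is a percentile (2.5 or 5 in standard use; other values
are accepted but marked non-standard) plus a z-limit mode. `exact`
uses the full-precision normal quantile (−1.95996…, −1.64485…);
`convention` uses the rounded limits −2 and −1.645 that interpretation
documents print. The convention mode is the default because that is how
the limits are applied in reporting practice.

Pattern flags compare the measured value strictly against its LLN
(exactly at the limit is normal): obstruction on the ratio, possible
restrictive pattern on FVC, decreased ventilatory capacity on FEV1, and
an isolated-reduced-FEV1 flag derived as FEV1 reduced with both others
normal. Tightening the percentile from 5 to 2.5 can only lower the LLN,
so the 2.5th-abnormal set is always a subset of the 5th-abnormal set —
asserted as a property test.

## Severity grading

Z-score scheme (LMS-family models): normal at or above the policy
z-limit; below it the bands run mild to −2, moderate to −2.5, moderately
severe to −3, severe to −4, very severe beyond. The published band
descriptions are open ranges, so a boundary convention is needed: normal
takes precedence at the LLN itself (consistent with strict abnormality),
and within the abnormal region each boundary belongs to the **more
severe** band (z = −2.5 grades moderately severe). Under the
2.5th-percentile convention limit of −2 the mild band is empty by
construction; under the 5th-percentile policy it spans (−2, −1.645).

Percent-of-predicted scheme (classical models): ≥ 80 normal, [65, 80)
moderate, [45, 65) moderately severe, [25, 45) severe, below 25 very
severe, with half-open bins whose upper edge is excluded (consistent
with the integer presentation "79–65 %"). The `harmonized` variant
relabels the ≥ 80 band *mild* so the scale aligns category-for-category
with the z-score scheme in severity-distribution views; because that
would label every normal subject mild, the `published` variant is the
default everywhere else. Each model family defaults to its own scheme;
cross-pairing is allowed but logged.

## Cohort statistics

Prevalence tables count a subject in every (sex, age-bin) stratum it
falls into; empty strata report n = 0 with prevalence marked undefined
(NaN), never silently 0. Evaluations outside a model's valid age range
are counted and reported in a parallel extrapolation column. Default
age bins for prevalence-by-age views are 21–29, 30–39, …, 70–74,
configurable. Rendered percentages use one decimal; returned frames
keep full precision.

Cohen's kappa is computed unweighted from the cross-tabulation
(κ = (p_o − p_e)/(1 − p_e)) and returns p_o and p_e alongside κ; the
degenerate case p_e = 1 (both classifications the same constant) raises
an explicit error rather than returning a number. Chi-square
(Pearson, no continuity correction) and the paired *t* delegate to
scipy, with guards for zero expected counts and zero-variance
differences. Between-model z-score differences are summarised per index
with the fraction of subjects beyond ±0.3 SD, the conventional limit
for a clinically significant between-model difference.

Records with FEV1 > FVC are physically impossible and are excluded from
cohort interpretation with a logged count (they remain available with
`drop_invalid=False`, which marginal-mode calibration requires — see
below).

## Synthetic cohorts

The generator emulates a two-centre general-population sample: strata of
633 and 695 subjects, male fraction 597/1328 (45.0 %), ages drawn per
sex from truncated normals on [21, 74] years with parameters 48.8/13.2
(male) and 48.2/12.9 (female), heights from normals 176.5/6.6 and
163.0/6.1 cm. Ages use truncated normals because only the means, SDs
and range of the emulated sample are known; note the truncation shifts
the realised mean about 0.3 years below the nominal parameter, so
calibration tests compare against the analytic truncated-normal moments
rather than the raw parameters. Centres carry no distributional effect
by default (the emulated sample pools them); per-centre overrides are
possible through separate configs.

Healthy lung indices are drawn so that z-scores under a designated
*truth* equation set are standard normal. Two modes exist because the
three indices cannot all be exactly standard normal at once when the
ratio is fev1/fvc:

* `index_consistent` (default): draw z(FVC) and z(ratio) (correlation
  configurable, default 0 for analytical tractability), convert to
  values, set FEV1 = ratio × FVC. Guarantees FEV1 ≤ FVC; the FEV1
  z-distribution is then only approximately standard normal.
* `marginal`: draw all three indices independently. Exact per-index
  calibration, at the price of internal inconsistency (fev1/fvc ≠ the
  stored ratio, and FEV1 may exceed FVC); used for calibration tests
  and stored with an explicit `ratio` column.

Ratio draws are truncated to (0.3, 1.0] by resampling, with a logged
count; this touches only the far tails of a healthy ratio distribution.

Disease components shift latent z-scores of a randomly chosen subset of
size round(prevalence × n): obstructive components shift z(ratio),
restrictive components z(FVC) (and z(FEV1) in marginal mode). The shift
is drawn N(mean, SD²), so SD = 0 is a pure location shift and SD > 0
inflates spread. Shifts that would leave the physical domain (ratio
outside (0.2, 1], non-positive volumes) are resampled with a logged
count. Truth labels (id, component, shift) are returned for recovery
tests, which check the classified prevalence against the closed-form
normal-mixture tail p·Φ(z* − shift) + (1 − p)·Φ(z*).

Fixture equation sets are physiologically plausible stand-ins for
published coefficient tables (which are deliberately not bundled):
medians rise with height with a ln-height power near 2 for volumes,
decline smoothly beyond age 25, S in ≈ 0.10–0.15, L in ≈ 0.7–1.3, on a
one-year age grid over 18–95. Coefficients are rounded to six decimals
at generation so that writing and re-loading a fixture reproduces the
in-memory model exactly, and a given seed always yields a byte-identical
file. The linear fixture is valid 18–65 years and carries the classical
percent-of-predicted cutoffs.

What the generator does **not** emulate: smoking status and symptoms,
measurement noise and quality-control failures, secular height trends,
between-centre demographic differences, and real covariance structure
between indices beyond the single configurable correlation. Passing
tests therefore demonstrate the correctness and calibration of the
interpretation machinery, not the representativeness of any real
population's prevalence estimates.

## Problem sizes and numerical choices

Calibration suites use n = 100,000 for demographic/LLN calibration
(3-standard-error and 3-binomial-SD acceptance bands), n = 20,000 for
disease-prevalence recovery at p ∈ {0.02, 0.05, 0.10}, and n = 10,000
for the Kolmogorov–Smirnov normality check (1 % critical value
1.628/√n). These sizes make the stochastic bands a few tenths of a
percentage point wide while keeping the full suite and the acceptance
script fast on a single CPU. The percentile/z functions are scipy's
erf-based normal CDF/quantile, checked to 1e−9 over z ∈ [−6, 6]; LLN
round-trips hold to 1e−9.

## Known limitations

* Published coefficient values of real reference equations are not
  bundled; users supply their own coefficient files in the documented
  dialect (the loader supports both families' shapes).
* The ratio is stored as a fraction and rendered as a percentage only in
  outputs; mixed conventions in input files are not auto-detected.
* Kappa is unweighted; ordinal (weighted) agreement on severity grades
  is not implemented.
* No confidence intervals on prevalence estimates.
* Only adult models: no paediatric branch, bronchodilator response, or
  other indices (FEF25–75, DLCO).
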