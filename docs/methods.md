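# Methods

## Measurement model

A histology observation is a count pair per patient, compartment and marker:
`n_marker_pos` marker-positive cells scanned, of which `n_y_pos` showed a
Y-chromosome signal. Two binomial thinning steps separate the biological
quantity of interest (the donor fraction *f*) from the observed count: the
section samples `n_marker_pos` cells from the compartment, and the in situ
hybridisation detects the Y chromosome in a truly male cell only with
probability *d* (nucleus truncation by the microtome). Hence
`E[n_y_pos / n_marker_pos] = d · f`, and an unbiased estimate of *f*
requires dividing the observed fraction by *d*.

### Detection-rate calibration

*d* is estimated from male control tissue, where *f* = 1 by construction,
as the **unweighted arithmetic mean of per-sample Y+ fractions** — each
control sample counts as one unit. Pooling counts instead would weight
samples by section size; on unbalanced controls the two differ (e.g.
fractions 1/2 and 90/100 give 0.70 unweighted but 0.892 pooled), and the
package deliberately implements, documents and tests the unweighted choice.
Calibration is per (compartment, marker); when a transplant marker lacks
marker-specific controls the compartment's pan-myeloid (Iba1) rate
substitutes, with an explicit `CalibrationFallbackWarning`. A rate of zero
(no control cell detected) aborts with `ZeroDetectionError` rather than
producing infinities.

### Correction

`corrected = raw / d`, applied per patient per compartment (each dot in a
kinetics plot is one patient). Values above 100 % are calibration
artifacts; they are clamped to 100 and flagged, never silently shrunk below
100. Clamped points are included in downstream regressions but counted in
the fit summary (`n_clamped`), since there is no principled exclusion rule.
Uncertainty in *d̂* is *not* propagated into the kinetics (an extension
point, noted, not implemented).

## Engraftment kinetics

Per compartment, ordinary least squares of corrected percent on
log10(days post-transplant):

    E[y] = b0 + b1 · x,   x = log10(t)

with adjusted R² (standard n − 2 correction) and a **one-sided** t-test of
b1 > 0 (engraftment can only accumulate). T50 is the inverse prediction at
50 %: `T50 = 10^((50 − b0)/b1)`, defined only for b1 > 0; a non-positive
slope returns a fit with T50 undefined and a non-significance flag rather
than an error.

### T50 confidence interval

The interval inverts the level-confidence band of the regression's **mean
response**: the two abscissae where

    b0 + b1·x ± t₍α/2,n−2₎ · s · sqrt(1/n + (x − x̄)²/Sxx)

crosses 50, back-transformed to days — the classical Fieller-type
calibration interval. The crossings are found numerically (bracketed
bisection via `brentq` on each side of the point estimate), which handles
the degenerate geometries uniformly: with zero residual variance the
interval collapses onto T50; when the slope is too shallow relative to its
uncertainty the lower band never re-crosses 50 and the upper bound is
reported as +infinity (the lower bound correspondingly as 0 when the upper
band never drops below 50). The interval is equivariant under time
rescaling: multiplying all days by c multiplies T50 and both bounds by
exactly c (tested as an invariant).

### Compartment comparison

One linear model over all compartments, `corrected ~ compartment × centred
log10(t)` (interaction included, so each compartment keeps its own slope).
Estimated marginal means are evaluated at the pooled mean log10-time —
centring makes each compartment's EMM its own intercept — and all pairwise
differences are tested with the studentized-range (Tukey) adjustment,
`p = SR.sf(|t|·√2, k, df_resid)`, floored at the unadjusted two-sided t
p-value. Compartments with fewer than `min_points` (default 3) points are
excluded with an audible `ExcludedGroupWarning`, never silently dropped.
The comparison is performed on engraftment responses, not on the T50
estimates themselves: responses keep the familiar linear-model machinery
(exact df, studentized range), whereas T50 is a nonlinear functional whose
sampling distribution is skewed at small n.

## Composition enrichment

For a clusters × conditions count table with grand total N, condition total
K, cluster size n and overlap k, the one-sided enrichment p-value is the
exact hypergeometric upper tail P(X ≥ k), computed by **tail summation in
log space** (`logsumexp` over log-pmf terms) — no normal approximation, so
small clusters are exact; agreement with direct fraction summation is
verified to 1e−12 for every table with N ≤ 30. By the upper-tail
definition P(X ≥ 0) = 1, so empty overlaps are never significant.
Benjamini–Hochberg runs across the **entire cluster × condition family**
(not per-condition columns). Depletion (lower tail) is available behind an
option, off by default. Star thresholds: p < 0.05 / 0.01 / 0.001 on the
adjusted value. A Marimekko-ready table (per-cluster condition proportions,
widths proportional to cluster size) is emitted alongside.

## Histology test batteries

- **Grubbs screening** — iterative two-sided Grubbs at α = 0.05 per group:
  the most extreme value is removed whenever G exceeds the t-quantile
  critical value `((n−1)/√n)·sqrt(t²/(n−2+t²))`, t = t(1−α/(2n), n−2),
  repeating until no rejection (or n < 3). Iteration is a deliberate
  choice; a single pass would leave masked pairs of outliers in place.
- **Kruskal–Wallis + Dunn** — tie-corrected H with chi-square reference;
  Dunn z-statistics on pooled mean ranks with the `Σ(t³−t)` tie correction;
  Holm–Bonferroni across all pairs. An all-identical input returns H = 0,
  p = 1 (scipy raises on this edge; the package defines it).
- **Pairwise tests** — Mann–Whitney U against a designated reference group,
  exact null distribution when the combined sample is ≤ 12 and untied,
  tie-corrected normal approximation otherwise, unadjusted by default (an
  optional Holm switch exists); or Welch t-tests (no variance pooling
  assumed) over all pairs with Holm adjustment.
- **Ward dendrograms** — agglomerative clustering of mean expression
  profiles under Ward's minimum-variance criterion on Euclidean distances
  (scipy linkage encoding; heights are non-decreasing). Missing entries are
  rejected — no imputation.

## Synthetic cohorts

The generator is the testing ground for everything above. Per compartment:
times are sampled **log-uniformly** over `time_range` so the log10
regressor is well spread (the distribution of real sampling times is not
knowable from a printed figure; log-uniform is a modelling choice), the
latent engraftment is the clamped line plus truncated Gaussian noise
(`residual_noise_sd`, default 10 percentage points — inter-individual
variability enters before counting), then two binomial stages (cell
sampling, Y detection) generate the counts. Controls are all-male tissue:
`Binomial(control_cells_per_section, d)`.

Defaults are the study conditions: four compartments with T50 = 51.52 (CP),
100 (LM), 150 (DM) and 264.55 d (PC) — range endpoints as reported for
choroid plexus and parenchyma, the middle two interpolated — slope 50
percent per log10-day, detection rate 0.8 per compartment, 12 patients per
compartment sampled between 30 and 1095 days, 100 cells per section
(studies count ≥ 50), 3 male controls of 200 cells each. Identical config +
seed gives byte-identical tables; the generating parameters are returned
(and written by the CLI) as a ground-truth sidecar keyed by seed.

What the generator does **not** emulate: spatial structure within sections
(detection loss is subsumed into *d*), repeated sections per patient
(one aggregated count per patient per compartment), correlated sampling
times across compartments of the same patient, and marker-dependent
detection differences (one marker by default). Passing tests therefore
demonstrate correctness of the estimators under the stated measurement
model, not robustness to those real-data features.

The composition generator drops `n_cells` into cluster × condition cells by
a single multinomial whose probabilities are proportional to
`condition_props`, equal cluster weights, and planted odds multipliers
(fold-enrichments); totals are conserved exactly.

## Numerical and design notes

- Band inversion brackets expand geometrically up to ±64 log10-units before
  declaring a bound unreachable (0 or +inf).
- A residual variance below 1e−12 · var(y) is treated as a noiseless fit.
- The Tukey-adjusted p is clipped into [p_unadjusted, 1]; at k = 2 the
  studentized-range and t references coincide.
- Exact Mann–Whitney switches to the asymptotic path at combined n > 12 or
  any tie, matching common practice for these sample sizes.
- Simulation sizes used by the test suite and acceptance script (200
  cohorts for recovery, 500 for calibration/coverage, 100 for power/size)
  were chosen to make the Monte-Carlo checks stable at the asserted
  tolerances while keeping the whole suite fast.

## Known limitations

- T50 estimates for fast compartments are mildly biased low when late
  observations saturate at 100 % (the clamp flattens the fitted slope);
  visible for the CP default (median estimate ≈ 42–50 d vs truth 51.5 d at
  12 patients). This is a property of the saturating measurement, not of
  the estimator, and disappears when sampling stops before saturation.
- The calibration interval treats the detection-rate correction as exact;
  coverage simulations (≈ 92–95 % empirically at the defaults) absorb the
  extra variability from estimating *d* with 3 controls.
- No mixed-effects patient terms and no nonlinear (saturating) turnover
  models — the log-linear form is the scope.
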