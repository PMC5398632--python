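# Methods

## Model and assumptions

The package models selection (or attainment classification) within an
age-banded cohort. A latent quality is assumed normal with unit variance
within any single birthday; its mean advances **linearly** by `A` standard
deviations over the cohort year. With birthtime `t ∈ [0, 1]` (0 = oldest
possible, 1 = youngest) and a fixed threshold `C` z-units above the oldest
children's mean, the selection probability is

```
p(t) = 1 − Φ(C + A·t).
```

Assumptions, and where they are testable:

* **Gaussianity with constant unit variance at every birthtime.** Not
  testable from grouped tail data alone; it is the identifying assumption
  that makes the probit of a tail proportion linear in `t`.
* **Linear travel.** Testable: the quadratic ΔR² F-test
  (`compare_models(..., "quadratic")`) probes curvature, which is also the
  signature a seasonal birth/ability cycle would leave.
* **Common slope across severity levels.** Testable via the
  birthtime × level interaction F-test.
* **Grouped-data midpoint convention.** The mean birthtime within an
  interval is taken at its midpoint; with ~monthly intervals and the
  modest curvatures the model allows, the grouping error is far below
  sampling noise.

`A` may be negative (declining qualities); the estimation machinery is
sign-agnostic, while the wastage geometry requires `A ≥ 0` and instructs
the caller to reverse the time axis otherwise.

## Calendars

Two year conventions reproduce the two printed midpoint sets exactly:
a 365-day year with February = 28 (monthly school-year analyses) and a
365.25-day year weighting 29 February by 0.25 (the tercile competition
year: 122 / 120.25 / 123 days). `custom_grid` accepts arbitrary day
lengths so quarters, halves and what-if splits need no new code.
Population pools are user inputs attached to intervals; where absent,
rating-table row totals serve as denominators (ratings treated as
exhaustive within the sampled children).

## Probit transformation

Upper-tail proportions are formed per interval × cumulative level; the
lowest level is everyone (p = 1) and is never transformed. Proportions of
exactly 0 or 1 have no finite probit; the default policy **excludes** the
point and records interval, level and reason, so ±∞ never enters a
regression silently. A continuity correction `p* = (x + 0.5)/(n + 1)` is
available by option for small-sample work. Fractional "counts" (shares ×
total selected, e.g. 320 × 0.57 = 182.4) are legal numerators: they are
expectations, and the probit needs only the ratio.

## Estimators

* **Endpoint:** per level, z(last interval) − z(first interval), averaged,
  then scaled to a full year. The default scale is `1/(t_last − t_first)`;
  for twelve monthly midpoints the package exposes the conventional
  whole-month ratio `MONTHLY_SPAN_SCALE = 12/11` (mid-September to
  mid-August spans 11 of 12 months). The two differ in the fourth decimal
  (365/334.5 vs 12/11); the constant keeps the monthly convention explicit
  rather than an approximation of the day-count ratio.
* **Per-level OLS:** z on t within each level; A = unweighted mean of
  slopes. Levels with fewer than two distinct birthtimes are skipped with
  a warning.
* **Stacked OLS:** all points at once, regressors t plus level dummies
  with the least severe level as reference; A is the t coefficient, C the
  intercept. Fits use statsmodels' QR-based least squares; rank-deficient
  designs are rejected naming the collinear column. On a balanced design
  (every level sharing the same birthtimes) the stacked slope equals the
  per-level mean exactly; the tests assert this.

OLS is **unweighted** by default: every probit point counts equally, which
is the convention the bundled worked examples follow. Weighting by the
approximate binomial information `n·φ(z)²/(p(1−p))` is available
(`weighted=True`) but off by default. By-cluster (per-interval) standard
errors are not implemented; the stacked residuals are correlated across
levels within an interval (see *Calibration* below), so the reported
p-values for A are mildly anti-conservative on multi-level rating data.

Model comparisons use the ΔR² F statistic
`F = (ΔR²/q) / ((1 − R²_full)/df_full)`; a ΔR² of exactly zero reports
F = 0, and a perfect full fit reports F = ∞ with p = 0.

## Metrics

`I_D`, `W`, `PopEx`, `PopCon` and the mean selected birthtime are evaluated
at exactly t = 0 and t = 1 from the fitted line — an extrapolation two
months beyond the outer tercile midpoints in the academy example, which is
why `I_D` (≈8.3) exceeds the naive first/last-tercile ratio (≈4.1). The
wastage baseline is the no-RAE horizontal at `p(0)`; no alternative
baseline is offered. The wastage integral has the closed form

```
∫₀¹ Φ(C + A·t) dt = [g(C + A) − g(C)] / A,   g(x) = x·Φ(x) + φ(x),
```

cross-validated in the tests against adaptive quadrature and a 10,001-node
Simpson oracle to 1e-8 over a parameter grid. `A = 0` returns `W = 0` by
convention (a flat curve wastes nothing); below `|A| < 1e-12` the closed
form is bypassed to avoid 0/0. Mean selected birthtime uses adaptive
quadrature (`scipy.integrate.quad`, tolerances 1e-12).

## Synthetic cohorts

The generator draws from the same forward model the estimators assume —
it emulates published-summary data shapes (per-interval binomial selection
counts; nested cumulative rating counts), not individual-level survey
microdata, covariates, or non-uniform seasonal birthrates. Its default
conditions mirror the bundled examples: classroom-like grids use 12 months
at roughly 450 children per month with criteria spanning the attainment
range; academy-like grids use the printed tercile pools. Nesting of
cumulative levels is enforced by construction: sequential conditional
binomials in `binomial` mode, a single latent quality per child in
`individual` mode. All randomness flows through one `numpy` generator
seeded from the spec (default seed 20170420, recorded in reports);
identical seeds give identical tables.

`recover_parameters` closes the loop (simulate → tabulate → probit →
stacked OLS). At classroom-like sizes the stacked estimator's mean bias in
A is below 0.02 over 1,000 replicates; at academy-like settings with
tenfold pools (which keep every tercile cell non-degenerate) it is below
0.03 over 200 replicates. Replicates with too few non-degenerate points
are dropped and counted. Monte-Carlo sizes in the tests (200–1,000
replicates) were chosen to make the checked bounds decisive at desk-scale
run times.

### Calibration of the F-tests

With *independent* probit points (single-level selection data), the
quadratic test's null rejection rate is within two points of its nominal
5% in the test suite. On nested multi-level rating tables the cumulative
columns share sampling noise, so the 48 stacked residuals are positively
correlated within months and the nominal F over-rejects (empirically
~11% at the 5% level under the null at classroom sizes). The calibration
property is therefore asserted on independent points; inference on nested
data should be read as approximate. This is a property of OLS-on-probit
pipelines generally, not of this implementation.

## Policy what-ifs

* **Relax criterion:** metrics at `C − ΔC`.
* **Split cohort (k):** each sub-cohort spans 1/k of the year; the quality
  still advances at the same per-annum rate, so within-cohort travel is
  `A/k` over the sub-cohort's own [0, 1]. This linear-travel assumption
  matches the quadratic test's routine failure to detect curvature. Two
  criterion rules: `fixed_c` (same z-distance threshold per sub-cohort,
  the default) and `fixed_intake` (a common per-sub-cohort criterion
  solved by bracketed root-finding to 1e-10 so the expected total selected
  matches the unsplit cohort). Under uniform births every sub-cohort
  behaves identically, so pooled and per-sub-cohort metrics coincide.
* **Rescale advancement:** metrics at `A·factor`, a crude model of
  selecting at a later age when annual advancement has attenuated.

## Numerical and rounding notes

Φ and Φ⁻¹ are scipy's double-precision implementations; no home-grown
approximations. Comparisons against the published renderings of the
worked examples are made at ±1 unit in the last printed digit, with two
documented exceptions where the published tables are internally
inconsistent at that precision (one probability cell that disagrees with
both its own frequencies and its printed z-score, and a day-1 selection
percentage whose printed value does not match the stated normal-tail
expression); in those cases the tests assert the value implied by the
published inputs and accept the published rendering within 1e-3.

## Limitations

* No uncertainty intervals on I_D or W (delta method / bootstrap not
  implemented); point estimates only.
* No ordinal cumulative-link maximum likelihood; OLS-on-probit is the
  method implemented, by design.
* No seasonal birthrate model; non-uniform pools enter only through
  user-supplied per-interval pool sizes.
* No clustered standard errors; see *Calibration*.
* No measurement error in birthtime; midpoints are treated as exact.
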