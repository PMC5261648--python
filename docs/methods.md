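# Methods

This note documents the statistical procedures, the synthetic-data
generator, the numerical choices, and the limits of what the test suite
demonstrates.

## Quantile-regression engine

`qr_engine.fit_quantile` minimises the pinball loss
ρ_τ(r) = r·(τ − 1{r<0}) over linear coefficients by solving the standard
primal split-residual LP (residuals split into non-negative u, v;
minimise τ·Σu + (1−τ)·Σv subject to y − Xβ = u − v) with the HiGHS
backend in `scipy.optimize.linprog`.  Regressors are internally centred
and scaled (and the response scaled) for conditioning; coefficients and
the objective are reported on the original scale.  The engine's contract
is the objective value: at degenerate sample sizes (τ·n integral) the
minimiser is an interval of order statistics and different backends may
return different vertices with identical loss.  Tests therefore compare
objectives against an exhaustive vertex-enumeration oracle (all
p-subsets of observations interpolated exactly), to 1e-8.

### Standard errors

The coefficient covariance uses the classical i.i.d.-error asymptotics
τ(1−τ)·s(τ)²·(XᵀX)⁻¹.  The sparsity s(τ) = 1/f(F⁻¹(τ)) is estimated by
the difference quotient of empirical residual quantiles over the
Hall–Sheather bandwidth at α = 0.05 — the default of the classical
quantile-regression software family, adopted here because no alternative
is dictated by the chart-construction problem itself.  When τ ± h leaves
(0,1), the bandwidth is shrunk to half the distance to the nearer
boundary.  A non-positive quantile spread raises a degenerate-sparsity
error; `fit_quantile` downgrades this to a diagnostic (saturated fits
have a point estimate but no inference).  Under longitudinal data with
within-subject tracking, repeated scans are positively correlated and
this i.i.d. covariance understates the variance; the calibration
simulations therefore use independent observations (see below), and
inference on tracked cohorts should be read as approximate.

Hypotheses on coefficients are tested with Wald χ² statistics
(Cβ)ᵀ(C·cov·Cᵀ)⁻¹(Cβ).  A likelihood-ratio variant is deliberately not
implemented: the Wald machinery covers every reported use.

## Estimated fetal weight and ratios

EFW uses Hadlock's third (HC/AC/FL) formula with lengths converted from
the package-wide mm convention to the formula's native cm.  Over the
physiological range (HC 80–370, AC 60–420, FL 8–85 mm) the formula is
strictly increasing in each argument — the AC·FL interaction term would
only reverse a partial derivative far outside that range.  EFW is kept at
full precision and rounded to integer grams only at chart emission.
FL/HC and FL/BPD are plain length ratios.  The bundled FL/HC and FL/BPD
reference tables print medians in the 0.56–0.97 range, roughly 3× the
ratio of the corresponding printed FL and HC medians; the source tables
define no rescaling, so the package computes plain ratios and bundles the
tables verbatim as separate reference data with no cross-table equality
asserted.

## Chart construction

* Analysis window: gestational days 98–286 inclusive (14w+0d to 40w+6d),
  so scans at the scheduled week-40 visit are retained; configurable.
* Outlier screen: per parameter, residuals of log value from a running
  median over 2-week GA bins; the MAD scale is pooled across bins
  (log-scale spread is nearly homogeneous in GA and per-bin MADs are too
  noisy at tens of scans per bin); a scan is dropped when the residual
  exceeds k × 1.4826 × MAD with k = 5 by default.  The rule is a gross-
  error screen, not a trimming device, and is configurable/disableable.
* Fitting is on the natural log (the base cancels on retransformation);
  GA is centred at 27 weeks before polynomial expansion — a pure
  conditioning choice with no effect on fitted values (verified by a
  centring-invariance test).
* Charts are evaluated at exact completed-week boundaries (w·7 days),
  exponentiated, monotone-rearranged within each week (idempotent,
  identity on non-crossing charts), and rounded: integer mm and g, two
  decimals for ratios.
* Default quantile grid {0.01, 0.025, 0.05, 0.10, 0.25, 0.50, 0.75,
  0.90, 0.95, 0.975, 0.99}: the union of the figure percentiles and the
  printed table columns.
* With covariates in the model, a chart is evaluated "at the average
  subject" (sample means of the covariate columns); with country terms,
  the all-countries curve is the share-weighted average of country rows.
  Table-style charts default to the no-covariate global model.

## Country and covariate comparisons

The country-minus-global difference at (τ, week) contrasts the
retransformed country fitted value with the share-weighted all-countries
value from the same joint model (the country remains in the pool); a
leave-one-out global is available as an option.  Variance is by the delta
method on the log-scale contrast; intervals are per-comparison 95% with
no multiplicity adjustment, and the exported tables carry a footnote to
that effect.  Covariate effects are reported per clinical unit — +10 y
age, +10 cm height, +10 kg weight, category contrasts for sex and parity
— as 100·(exp(unit·β)−1) percent, with single-coefficient Wald tests.

## Bundled reference charts

Twelve chart CSVs (five biometry parameters, EFW overall and by fetal
sex, two head ratios, sex-specific birthweight) plus two study-design
count tables ship under `fetalgrowth/data/` with a SHA-256 manifest;
`load_bundle` verifies it by default.  Lookup snaps to exact cells
(`chart_value`) or interpolates: linear in GA between week rows, then
piecewise-linear inversion of the value/percentile profile at that GA.
Both day-interpolating and completed-week placement modes exist;
interpolation is the default.  Values outside the printed percentile
range are clamped to the boundary percentile and flagged — extreme-tail
extrapolation from a weekly grid has no statistical support.  The
normal-equivalent z is a reporting convenience only; the charts are
distribution-free.  Where integer rounding makes neighbouring printed
cells equal, the percentile of that shared value is not unique; the
round-trip guarantee is exact percentile recovery at strictly interior
cells and value-level consistency at ties.  Within-week monotonicity
holds for every bundled table; across-week monotonicity is *not*
asserted (the printed HL 2.5th percentile dips from week 39 to 40).

The quartile-asymmetry summary of the bundled EFW chart is +0.111 at 15
completed weeks (quartiles 106/114/124 g) and −0.016 at 40 weeks
(3,333/3,617/3,892 g).  The source text pairs these two numbers with the
opposite week labels; the quartiles themselves are unambiguous, and the
package reports the values as computed from the printed quartiles.

## Synthetic cohort generator

The generator reproduces the study design: ten countries × 140 women,
visits scheduled at 14/18/24/28/32/36/40 weeks with uniform ±1-week
jitter (so some scans fall just outside the analysis window, as in a real
cohort), triplicate measurements reduced to a median and rounded to
0.1 mm, 10% independently missed visits, 3.6% consent withdrawal (no
scans contributed) and 3.2% loss to follow-up (truncation after a random
visit).

EFW is quantile-parametrised: a subject keeps one latent uniform rank r
across visits (individuals track along centiles; a scan-level rank
re-draw is available for calibration studies), and

    log EFW = m(g) + σ·(z + c(t)·z²) + Σ βₖ(r)·xₖ + d_country,
    z = Φ⁻¹(r) clipped to ±4.5.

* m(g): cubic in centred GA fitted to the bundled WHO EFW median column
  (so the default synthetic population grows along the WHO median).
* σ = 0.112: mean log-scale quartile spread of the bundled EFW chart.
* c(t): linear in GA between two anchors solved so the original-scale
  Bowley coefficient is −0.02 at 15 weeks and +0.11 at 40 weeks — the
  drift from slight left-skew to clear right-skew reported for EFW.
* Covariate effect profiles βₖ(r) interpolate linearly in the rank
  between a lower- and upper-tail magnitude: sex 3.5→4.5% (male vs
  female), age 3→2% per +10 y, height 2→1% per +10 cm, weight 1→1.5% per
  +10 kg, parity 1.5→1% (the source states both "1–1.5%" and "1–3%" for
  parity; the smaller range is used).
* Country effects default to an illustrative ±5% multiplicative spread
  (ordered India lowest to Norway highest); they are not estimates of
  the real country contrasts, and country-comparison tests set effects
  explicitly.
* Maternal covariates are drawn from families calibrated to the study's
  summary quartiles (age ~ N(28, 4.45²) clipped to 18–40; height ~
  N(163, 8.2²); weight ~ logN(log 61, 0.157²); 42% parous; 53.2% male),
  an explicit distributional choice since only quartiles are printed.

Because m is cubic and c linear in GA, every conditional log-quantile is
exactly cubic in GA: the fitting model is well specified, and
`true_quantile` gives closed-form truth for recovery tests.  The same
map generates the data (rank → value), so empirical quantiles of large
samples match `true_quantile` by construction (verified at n = 10⁶ to
0.5%).

Biometry is decomposed from the EFW target by scaling smooth cubic
log-median profiles (fitted to the bundled biometry charts) by a common
factor; on the cm scale the Hadlock log10 is quadratic in that factor,
so the increasing-branch root is closed form.  Only EFW-level truth is
asserted in recovery tests — the per-parameter correlation structure of
real biometry (e.g. head-sparing patterns) is not modelled.

### What the generator does not emulate

Measurement error is homoscedastic on the log scale and independent
across parameters and visits; real sonographer error is operator- and
center-dependent.  Attrition is independent of fetal size (no informative
dropout).  Within-subject tracking is a single constant rank — real
fetuses cross centiles.  Passing recovery tests therefore demonstrates
correctness of the estimation pipeline under the stated generative
model, not clinical validity on real cohorts.

## Calibration simulations (problem sizes)

Coverage of the country-difference CI is checked over 300 replicates of
3 countries × 100 subjects × 3 visits; Wald type-I error over 500
replicates of 3 × 50 × 3.  These use a linear log-median base curve with
a degree-1 GA model (correct specification) and scan-level ranks
(independent observations) — the regime the i.i.d. asymptotics assume —
with sizes chosen so the asymptotics are adequate while hundreds of
replicates stay fast.  Chart recovery uses the full study design (1,400
subjects, 7 visits, subject-level tracking, default noise and attrition)
with country/covariate effects off so the marginal distribution equals
the reference-covariate truth; the fitted 10th/50th/90th curves agree
with `true_quantile` within 2% at every week (observed max ≈ 1.4%,
Monte-Carlo se ≈ 0.5–1% depending on week and tail).  Covariate recovery
reports quartile-level (τ = 0.25/0.5/0.75) effects, where the
Monte-Carlo se at this design (~0.35 pp) makes the ±0.8 pp tolerance a
≥2σ band; tail quantiles (τ = 0.1/0.9) have se ≈ 0.5–0.7 pp at the same
size and are checked loosely elsewhere.

## Known limitations

* No crossing-penalised joint estimation or smoothing splines; the
  polynomial-plus-rearrangement route matches the published approach.
* The i.i.d. sparsity covariance ignores within-subject correlation
  (see above); a cluster-robust variant would be the natural extension.
* Conditional (velocity) charts from repeated measures are out of scope.
* The CLI `compare` command refits the country model from cohort files
  rather than consuming a serialized fit: fits hold numpy state whose
  persistence format would outlive its usefulness, and refitting is
  cheap at these sizes.
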