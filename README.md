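# fetalgrowth

Distribution-free fetal growth references from longitudinal ultrasound
biometry — a reusable implementation of the quantile-regression pipeline
behind multinational fetal growth charts, with the published WHO fetal
growth charts bundled for clinical percentile lookup.

## Who this is for

Perinatal epidemiologists and biostatisticians who need to (re)build
gestational-age reference intervals from cohort data, validate chart
methodology on synthetic cohorts with known truth, or place individual
ultrasound measurements on the WHO charts programmatically.

## The model

For a biometric parameter or estimated fetal weight (EFW) `y` measured at
gestational age `t` (weeks), the τ-th conditional quantile is modelled on
the log scale as a polynomial in centred gestational age,

    Q_{log y}(τ | t) = β₀(τ) + β₁(τ)·g + β₂(τ)·g² + β₃(τ)·g³,   g = t − 27,

optionally extended with additive covariate terms (fetal sex, maternal
age/height/weight, parity) and country indicators with GA × country
interactions.  Each β(τ) is estimated independently by minimising the
pinball loss ρ_τ(r) = r·(τ − 1{r<0}) — an exact linear program, no
distributional assumption — then retransformed by exponentiation,
rearranged within week so percentile curves cannot cross, and rounded into
a publishable chart.  Inference (Wald χ² tests, delta-method CIs for
country-vs-global percentile differences) uses the asymptotic normality of
quantile-regression estimates with a Hall–Sheather sparsity estimate.

EFW itself is Hadlock's third formula (HC, AC, FL in cm):

    log₁₀ EFW[g] = 1.326 − 0.00326·AC·FL + 0.0107·HC + 0.0438·AC + 0.158·FL

Quartile asymmetry of a fitted distribution is summarised by the Bowley
coefficient ((Q3−Q2) − (Q2−Q1)) / (Q3−Q1).

## Worked example

Simulate a small ten-country cohort, fit an EFW chart, and place two
measurements on the bundled WHO charts:

```sh
$ fetalgrowth simulate --seed 1 --n-per-country 25 --out cohort
[fetalgrowth 0.1.0] wrote 250 subjects -> cohort/subjects.csv, 1500 scans -> cohort/scans.csv

$ fetalgrowth fit --cohort cohort --parameter efw --taus 0.1,0.5,0.9 --out efw_chart.csv
[fetalgrowth 0.1.0] wrote chart (27 weeks x 3 percentiles) -> efw_chart.csv

$ head -4 efw_chart.csv
# parameter=efw,unit=g,stratum=,provenance=fitted
week,p10,p50,p90
14,79,92,103
15,99,116,132
```

Each chart row is one completed gestational week; the columns are the
fitted 10th/50th/90th EFW percentiles in grams (at 14 weeks the synthetic
population's median fetus weighs 92 g, close to the WHO chart's 90 g).

```sh
$ fetalgrowth lookup --parameter efw --ga-days 224 --value 1500
percentile 3.4  z -1.825

$ fetalgrowth lookup --parameter efw --ga-days 280 --value 2600 --sex female
percentile 5 (below-min)  z -1.645
```

A 1,500 g fetus at 32 weeks sits at the 3.4th percentile of the bundled
WHO EFW chart (z ≈ −1.83): small for gestational age by the usual 10th-
percentile cutoff.  A 2,600 g female fetus at 40 weeks falls below the
lowest printed percentile of the sex-specific chart and is flagged rather
than extrapolated.

The same operations are available as a library
(`fetalgrowth.chart_builder.construct_chart`,
`fetalgrowth.reference_charts.percentile_of`, ...), which is the surface
the test suite exercises.

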