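# fracrisk

Absolute fracture-risk prediction and external-validation toolkit for
osteoporosis epidemiology.

`fracrisk` implements a Garvan-style fracture risk calculator — the
individualized 5- and 10-year probabilities of hip and of any non-vertebral
osteoporotic fracture for women and men aged 60+, in two variants (one
using femoral-neck BMD, one substituting body weight) — together with the
statistical machinery needed to validate such a calculator on an
independent cohort:

- incidence rates per 1000 person-years with exact Poisson intervals,
- ROC discrimination (Mann–Whitney AUC, DeLong standard errors, paired
  DeLong comparison of the BMD and weight models),
- quantile calibration (mean predicted risk vs Kaplan–Meier observed
  cumulative incidence per quintile/quartile of predicted risk),
- geometric-mean predicted-risk ratios between fracture and non-fracture
  subjects, and
- categorical net reclassification improvement (NRI) with Pencina
  standard errors,

plus a synthetic-cohort generator whose event process is driven by the risk
model itself, so the entire validation pipeline is testable end to end with
known ground truth. It is aimed at biostatisticians and epidemiologists
who build or audit prognostic fracture models.

## The model

For each outcome (hip, any osteoporotic), sex and variant the calculator is
a Cox-type survival model with a fixed baseline survival at the two
horizons. With linear predictor

```
η = β_age (age − a₀) + β_bmd (T − T₀)        [or β_wt (w − w₀)]
    + s_fx[k] + s_fall[j]
```

where `T` is the femoral-neck T-score, `k ∈ {0,1,2,3+}` counts prior
low-trauma fractures and `j ∈ {0,1,2,3+}` falls in the last 12 months, the
absolute risk at horizon `t ∈ {5, 10}` years is

```
risk(t) = 1 − S₀(t)^exp(η)
```

Coefficients ship as a versioned, human-readable YAML document
(`src/fracrisk/data/garvan_coefficients.yaml`, a documented reconstruction
of the published model structure) that also carries the sex-specific
young-adult reference constants converting BMD (g/cm²) to T-scores.
Counts above the top category clamp down to it; horizons other than 5 and
10 years and ages outside [50, 110] are rejected rather than extrapolated.

## Worked example

```
$ fracrisk predict --age 70 --sex F --tscore -2.0 --fractures 1 --falls 1 \
    --outcome hip --outcome any --horizon 5 --horizon 10 --variant bmd
hip 5-year risk (bmd model): 7.5%
hip 10-year risk (bmd model): 13.1%
any_osteoporotic 5-year risk (bmd model): 23.5%
any_osteoporotic 10-year risk (bmd model): 41.7%
```

A 70-year-old woman with osteopenic bone density (T-score −2.0), one prior
fragility fracture and one fall in the past year has a 13.1% probability of
hip fracture within 10 years under the BMD model — a high-risk profile by
most intervention thresholds — and a 41.7% probability of any
non-vertebral osteoporotic fracture.

The same library drives cohort-level work:

```
$ fracrisk simulate --n 2000 --seed 42 --out cohort.csv
wrote 2000 subjects to cohort.csv
$ fracrisk validate --cohort cohort.csv --out-dir validation --horizons 10
validation tables written to validation
$ head -3 validation/incidence.csv
sex,outcome,n,events,person_years,rate_per_1000py,ci_low,ci_high
female,any_osteoporotic,1091,221,7323.0,30.2,26.3,34.4
female,hip,1091,71,7943.3,8.9,7.0,11.3
```

`validate` writes one delimited table per analysis (incidence,
discrimination, calibration, risk ratios, reclassification) per sex,
outcome, model variant and horizon, plus a log of any subjects excluded for
missing predictors. Every NRI row carries its sign convention (positive =
the weight model classifies better) so the tables cannot be misread.

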