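# Garvan-style absolute fracture-risk coefficients
# -------------------------------------------------
# One block per (outcome x sex x variant).  Each block defines a Cox-model
# linear predictor
#
#     eta = age_per_year * (age - age_center)
#         + tscore_per_sd * (tscore - tscore_center)      [bmd variant]
#           | weight_per_kg * (weight - weight_center)    [weight variant]
#         + prior_fracture_scores[k]   (k = prior low-trauma fractures, top 3+)
#         + falls_scores[j]            (j = falls in last 12 months, top 3+)
#
# and two baseline survival constants, so that the absolute risk at horizon
# t in {5, 10} years is
#
#     risk(t) = 1 - baseline_survival[t] ** exp(eta).
#
# The T-score reference block converts femoral-neck BMD (g/cm^2) to a
# T-score via  t = (bmd - young_adult_mean) / young_adult_sd  (sex-specific,
# GE Lunar densitometry); override it when another reference population is
# appropriate for the densitometer in use.
#
# PROVENANCE: this is a reconstruction, not a verbatim vendor export.  The
# functional form and predictor categories follow the published Dubbo
# Osteoporosis Epidemiology Study prognostic models behind the Garvan
# Fracture Risk Calculator (hip and any fragility fracture, women and men,
# BMD and body-weight variants).  Per-SD / per-year log-hazard slopes sit at
# the hazard ratios reported for that development cohort; the baseline
# survival constants are anchored so that a Norwegian-style cohort of
# 60+-year-olds is assigned median 10-year risks of roughly 18% / 3.6%
# (women, any / hip) and 9.8% / 1.2% (men).  Versioned so any retranscription
# is diff-able.

version: "garvan-recon-1.0"
source: >-
  Reconstructed from the published Dubbo Osteoporosis Epidemiology Study
  prognostic models for hip and any fragility fracture (Garvan Fracture
  Risk Calculator), Cox proportional-hazards form with fixed 5- and 10-year
  baseline survival.

tscore_reference:
  female: {young_adult_mean: 0.97, young_adult_sd: 0.095}
  male: {young_adult_mean: 1.05, young_adult_sd: 0.122}

models:
  hip:
    female:
      bmd:
        age_per_year: 0.067
        age_center: 70.0
        tscore_per_sd: -0.69
        tscore_center: -1.5
        prior_fracture_scores: [0.0, 0.65, 1.00, 1.30]
        falls_scores: [0.0, 0.35, 0.65, 1.00]
        baseline_survival: {5: 0.980, 10: 0.964}
      weight:
        age_per_year: 0.071
        weight_per_kg: -0.028
        weight_center: 69.0
        prior_fracture_scores: [0.0, 0.65, 1.00, 1.30]
        falls_scores: [0.0, 0.35, 0.65, 1.00]
        age_center: 70.0
        baseline_survival: {5: 0.979, 10: 0.962}
    male:
      bmd:
        age_per_year: 0.067
        age_center: 70.0
        tscore_per_sd: -0.62
        tscore_center: -0.95
        prior_fracture_scores: [0.0, 0.65, 1.00, 1.30]
        falls_scores: [0.0, 0.35, 0.65, 1.00]
        baseline_survival: {5: 0.994, 10: 0.988}
      weight:
        age_per_year: 0.071
        weight_per_kg: -0.020
        weight_center: 80.0
        prior_fracture_scores: [0.0, 0.65, 1.00, 1.30]
        falls_scores: [0.0, 0.35, 0.65, 1.00]
        age_center: 70.0
        baseline_survival: {5: 0.9895, 10: 0.980}
  any_osteoporotic:
    female:
      bmd:
        age_per_year: 0.055
        age_center: 70.0
        tscore_per_sd: -0.40
        tscore_center: -1.5
        prior_fracture_scores: [0.0, 0.55, 0.85, 1.10]
        falls_scores: [0.0, 0.25, 0.45, 0.65]
        baseline_survival: {5: 0.906, 10: 0.820}
      weight:
        age_per_year: 0.058
        weight_per_kg: -0.018
        weight_center: 69.0
        prior_fracture_scores: [0.0, 0.55, 0.85, 1.10]
        falls_scores: [0.0, 0.25, 0.45, 0.65]
        age_center: 70.0
        baseline_survival: {5: 0.903, 10: 0.815}
    male:
      bmd:
        age_per_year: 0.055
        age_center: 70.0
        tscore_per_sd: -0.42
        tscore_center: -0.95
        prior_fracture_scores: [0.0, 0.55, 0.85, 1.10]
        falls_scores: [0.0, 0.25, 0.45, 0.65]
        baseline_survival: {5: 0.947, 10: 0.902}
      weight:
        age_per_year: 0.058
        weight_per_kg: -0.015
        weight_center: 80.0
        prior_fracture_scores: [0.0, 0.55, 0.85, 1.10]
        falls_scores: [0.0, 0.25, 0.45, 0.65]
        age_center: 70.0
        baseline_survival: {5: 0.944, 10: 0.900}
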