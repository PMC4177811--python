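# Default synthetic-cohort configuration (YAML).
# Emulates a Norwegian population-based cohort of women and men aged 60+:
# sex-specific age, femoral-neck BMD (g/cm^2, mean anchored at age 70 with a
# linear age slope), body weight (kg) correlated with BMD, and categorical
# prior-fracture (0..3+) and 12-month fall (0..2) distributions.  Mortality
# and administrative censoring give a mean follow-up of ~7 years over an
# ~8-year registration window.

n: 3000
seed: 42
sex_fraction_female: 0.547

age:
  female: {mean: 69.3, sd: 6.3}
  male: {mean: 69.7, sd: 5.7}
age_range: [60.0, 90.0]

bmd:
  female: {mean: 0.828, sd: 0.12, age_slope_per_year: -0.004}
  male: {mean: 0.939, sd: 0.13, age_slope_per_year: -0.003}

weight:
  female: {mean: 69.1, sd: 11.8}
  male: {mean: 80.7, sd: 11.7}
weight_bmd_correlation: 0.3

prior_fracture_probs:
  female: [0.742, 0.155, 0.070, 0.033]
  male: [0.900, 0.074, 0.020, 0.006]
falls_probs:
  female: [0.691, 0.296, 0.013]
  male: [0.684, 0.299, 0.017]

mortality_rate: 0.02
admin_censor_years: 8.2
noise_sd_weight_channel: 0.4
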