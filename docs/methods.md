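# Methods

## The risk model

The engine evaluates survival-model nomograms of the Garvan type: for each
outcome (hip fracture; any non-vertebral osteoporotic fracture, i.e. all
non-vertebral low-trauma fractures except fingers, toes and skull), sex and
predictor variant, absolute risk over horizon *t* ∈ {5, 10} years is

    risk(t) = 1 − S₀(t)^exp(η),

a proportional-hazards form with a fixed baseline survival per horizon.
The linear predictor is additive in age (per year, centred at 70),
femoral-neck bone density expressed as a T-score (BMD variant) or body
weight in kg (weight variant), and category scores for prior low-trauma
fractures since age 50 and for falls in the preceding 12 months. Both
counts use four ordered categories (0, 1, 2, 3+); counts above the top
category are clamped down to it, because the equations define scores only
for their listed categories. Each clamp is reported through the package
logger so batch runs can audit it.

The coefficient document is data, not code: a versioned YAML file with one
block per outcome × sex × variant, each holding the slopes, category
scores and the 5- and 10-year baseline survivals, plus sex-specific
young-adult reference constants (mean, SD in g/cm²) that interconvert BMD
and T-scores. The shipped file is an openly labelled *reconstruction* of
the published Dubbo-cohort model structure: the per-unit log-hazard slopes
sit at that model family's reported hazard ratios (≈2.0/SD of femoral-neck
BMD for hip fracture, ≈1.5/SD for any fracture, ≈1.4 per 5 years of age,
graded category scores for prior fractures and falls), and the baseline
survivals are anchored so a Norwegian-style 60+ cohort receives median
10-year risks of roughly 18%/3.6% (women, any/hip) and 9.8%/1.2% (men).
Loading validates completeness (a missing block or horizon fails loudly,
naming the block) and every numeric field; serialization round-trips, and
the test suite pins the file's SHA-256 so silent edits are impossible.

Numerical guards: predicted probabilities are clipped to
[1e−12, 1 − 1e−12]. For extreme but admissible profiles exp(η) is large
enough that 1 − S₀^exp(η) rounds to 1.0 in double precision although the
model's risk is strictly below 1; the clip keeps downstream log-scale
statistics (risk ratios, logit CIs) well defined. Horizons other than 5
and 10 years are rejected, not interpolated, and age outside [50, 110] is
an error, not an extrapolation — the source models were fitted in elderly
cohorts and say nothing outside that range.

## Validation statistics

**Incidence.** First incident fractures divided by summed person-years,
scaled to 1000. Hip and any-fracture analyses carry separate follow-up
columns because censoring at first fracture differs by outcome. The
default interval is the exact Poisson (chi-square/gamma quantile) form,
chosen over the log-normal approximation because it behaves correctly at
zero and small counts; the approximation is available as an option.

**Discrimination.** AUC is the Mann–Whitney probability that a fracture
case outranks a non-case, ties counted 1/2 — exactly the pairwise
enumeration the tests brute-force. Standard errors use DeLong placement
values; the BMD-vs-weight comparison uses the paired DeLong covariance
with a two-sided normal p-value. The default outcome is "suffered a first
fracture during follow-up"; a horizon-restricted mode (events within the
horizon; subjects censored event-free before it excluded) is provided and
labelled, since censoring handling for horizon-specific AUCs is a genuine
analytic choice. Confidence intervals are normal on the AUC scale
truncated to [0, 1], with a logit-scale option.

**Calibration.** Subjects are grouped by empirical quantiles of predicted
risk — quintiles for any-osteoporotic fracture, quartiles for hip, with
ties assigned to the lower group — and each group's mean predicted risk is
compared with the observed cumulative incidence at the horizon. Observed
risk defaults to the Kaplan–Meier complement (death and administrative
end-of-registration treated as censoring), because mean follow-up in the
cohorts this emulates (~7 years) is shorter than the 10-year horizon and a
crude proportion would be biased low; the crude estimator is available and
is the one that exhibits competing-risk over-estimation (below). Under
perfect calibration a group's observed risk is a heterogeneous-Bernoulli
mean, giving the Monte-Carlo band mean ± z·√(Σpᵢ(1−pᵢ))/n used by the
calibration-by-construction checks.

**Predicted-risk ratio.** Geometric-mean ratio of predicted risk between
fracture and non-fracture subjects: exp of the difference in mean log
predicted risk, with a Welch two-sample interval on the log scale
(back-transformed) because the two groups' log-risk variances differ.
It is scale-equivariant: rescaling all predictions leaves it unchanged.

**Reclassification.** Categorical NRI of a comparison model against a
reference model. By default each model's own predicted-risk quartiles
define its risk categories, matching the convention of using "the
quartiles of the predicted risk from both models" as thresholds; a shared
(pooled-quartile) mode and fully explicit thresholds exist because the
model-specific reading is not the only defensible one, and outputs label
which was used. Components are net proportions moved in the correct
direction (up for events, down for non-events); standard errors are
Pencina's asymptotic forms, p-values two-sided normal. The sign convention
— positive means the comparison model classifies better — is embedded in
every result object and printed in every output table. Swapping the two
models negates all three components exactly, and the vector and cross-tab
computation paths agree exactly; both are tested.

## The synthetic cohort generator

The generator emulates a population-based Norwegian-style cohort of women
and men aged 60+ (file `tromso_like.cfg`): truncated-normal age (women
69.3 ± 6.3 y, men 69.7 ± 5.7 y, range 60–90), femoral-neck BMD with a
linear age slope (−0.004/−0.003 g/cm² per year; pooled means ≈0.83/0.94
g/cm², SD 0.12/0.13), body weight (69 ± 12 / 81 ± 12 kg) correlated 0.3
with BMD, prior-fracture category probabilities (women
0.742/0.155/0.070/0.033; men 0.900/0.074/0.020/0.006) and fall
probabilities (≈0.69/0.30/0.015 in both sexes). Default mortality 0.02
deaths per person-year and administrative censoring at 8.2 years give mean
follow-up near 7 years; the sex mix is 54.7% women. These defaults are the
study conditions, not tuning knobs.

Event times come from the model itself: each subject receives a constant
fracture hazard λ = −ln(1 − p₁₀)/10 calibrated so the 10-year cumulative
incidence equals their model-predicted 10-year any-osteoporotic risk (BMD
variant is the data-generating truth). A constant hazard is the minimal
process consistent with the model, which pins down only the 5- and 10-year
cumulative risks; the implied 5-year risk, 1 − (1 − p₁₀)^½, is close to
but not exactly the model's own 5-year prediction, and 5-year analyses on
synthetic data inherit that approximation. Hip events are a thinned subset
of any-fracture events with subject probability p_hip/p_any (clamped to
[0, 1]), preserving the nesting of outcomes. Death is an independent
exponential time; observed follow-up is the minimum of fracture, death and
administrative censoring. One `numpy` generator seeded from the config
drives every draw, so identical configs give byte-identical cohorts.

What the generator does *not* emulate: treatment effects, secular trends,
longitudinal BMD change, within-person fall/fracture clustering beyond the
category draws, age-dependent mortality, and real miscalibration of the
model itself (events are generated *from* the model, so calibration holds
by construction). Passing calibration tests therefore demonstrates that
the pipeline estimates what it should when the model is true — not that
the shipped coefficients are accurate for any real population. Degrading a
prediction vector with log-scale Gaussian noise (a Gaussian shift of log p
renormalized against the complementary mass, i.e. a logit shift; sd 0.4 by
default) provides a controlled information-loss channel for the
directional BMD-vs-weight comparisons: the degraded channel loses AUC and
earns a negative overall NRI against the intact model, the qualitative
pattern expected when body weight replaces measured BMD.

## Problem sizes and reproducibility

The calibration-by-construction check uses one 20,000-subject cohort with
mortality 0 and censoring at 10 years (≈4,000 per quintile, Monte-Carlo SE
≈0.6 percentage points per group); the directional comparisons use 50
replicates of 2,000 subjects with degradation sd 0.4. Spot checks across
seeds show the per-group 95% band achieving nominal coverage (3 misses in
60 group-checks). The acceptance script re-derives all of its quantities
at run time from a single `--seed`.

## Known limitations

- The shipped coefficient file is a structural reconstruction, versioned
  and checksummed so any retranscription against a primary source is a
  one-file, fully diff-able change; absolute risk levels should not be
  used clinically as-is.
- Hip follow-up after a non-hip fracture continues to death/censoring with
  no further hip-event opportunity in the simulator; hip KM estimates
  remain consistent (censoring is independent) but hip hazards are not
  constant after a non-hip event.
- The quantile calibration table treats death as censoring; it estimates
  net (hypothetical no-death) risk. Observed-vs-predicted deficits caused
  by competing mortality are visible through the crude estimator option,
  not the default.
- No time-dependent (inverse-probability-weighted) AUC, continuous NRI,
  or formal goodness-of-fit test; the toolkit mirrors a
  quantile-concordance validation design.
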