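"""Risk-engine contract: bounds, monotonicity, unit equivalence, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fracrisk import RiskProfile, predict_cohort, predict_risk
from fracrisk.errors import (
    MissingPredictorError,
    ProfileError,
    UnsupportedHorizonError,
)

# ---------------------------------------------------------------------------
# Reference panel: eight profiles spanning both sexes, outcomes and variants.
# Expected probabilities are frozen regression pins; each test case is also
# re-derived independently in-line from the coefficient document's fields via
# risk = 1 - S0(t)^exp(eta), without going through the engine's evaluator.
# ---------------------------------------------------------------------------
PANEL = [
    # (profile kwargs, outcome, horizon, variant, expected probability)
    (dict(sex="female", age=70, t_score=-2.0, prior_fractures=1, falls_12mo=1),
     "hip", 10, "bmd", 0.1312702670379523),
    (dict(sex="female", age=65, femoral_neck_bmd=0.83),
     "any_osteoporotic", 5, "bmd", 0.07151101137504706),
    (dict(sex="female", age=80, weight=60.0, prior_fractures=2, falls_12mo=1),
     "hip", 10, "weight", 0.32366916391326894),
    (dict(sex="female", age=75, weight=72.5, falls_12mo=2),
     "any_osteoporotic", 10, "weight", 0.331407830415711),
    (dict(sex="male", age=70, t_score=-1.0),
     "hip", 5, "bmd", 0.006188327304473971),
    (dict(sex="male", age=78, femoral_neck_bmd=0.78, prior_fractures=1),
     "any_osteoporotic", 10, "bmd", 0.37613575745445454),
    (dict(sex="male", age=85, weight=85.0, prior_fractures=3, falls_12mo=2),
     "hip", 10, "weight", 0.31113912906008284),
    (dict(sex="male", age=62, weight=95.0),
     "any_osteoporotic", 5, "weight", 0.028519714990691006),
]


@pytest.mark.parametrize("kwargs,outcome,horizon,variant,expected", PANEL)
def test_reference_panel(coeffs, kwargs, outcome, horizon, variant, expected):
    profile = RiskProfile(**kwargs)
    est = predict_risk(profile, outcome, horizon, variant, coeffs)

    # independent hand evaluation of the transcribed equation
    block = coeffs.block(outcome, profile.sex, variant)
    eta = block.age_per_year * (profile.age - block.age_center)
    if variant == "bmd":
        if profile.t_score is not None:
            t = profile.t_score
        else:
            ref = coeffs.tscore_reference[profile.sex]
            t = (profile.femoral_neck_bmd - ref.young_adult_mean) / ref.young_adult_sd
        eta += block.tscore_per_sd * (t - block.tscore_center)
    else:
        eta += block.weight_per_kg * (profile.weight - block.weight_center)
    eta += block.prior_fracture_scores[min(profile.prior_fractures, 3)]
    eta += block.falls_scores[min(profile.falls_12mo, 3)]
    by_hand = 1.0 - block.baseline_survival[horizon] ** math.exp(eta)

    assert est.probability == pytest.approx(by_hand, abs=1e-10)
    assert est.probability == pytest.approx(expected, rel=1e-12)


def _grid_profiles(sex):
    for age in (60, 70, 80, 95):
        for t in (-3.5, -2.0, -0.5, 1.0):
            for w in (45.0, 70.0, 95.0):
                for fx in (0, 1, 3):
                    for falls in (0, 2):
                        yield RiskProfile(
                            sex=sex, age=age, t_score=t, weight=w,
                            prior_fractures=fx, falls_12mo=falls,
                        )


@pytest.mark.parametrize("sex", ["female", "male"])
@pytest.mark.parametrize("outcome", ["hip", "any_osteoporotic"])
@pytest.mark.parametrize("variant", ["bmd", "weight"])
def test_bounds_and_horizon_ordering_on_grid(coeffs, sex, outcome, variant):
    """All predictions lie in (0,1) and 10-year risk >= 5-year risk."""
    for profile in _grid_profiles(sex):
        p5 = predict_risk(profile, outcome, 5, variant, coeffs).probability
        p10 = predict_risk(profile, outcome, 10, variant, coeffs).probability
        assert 0.0 < p5 < 1.0 and 0.0 < p10 < 1.0
        assert p10 >= p5


@pytest.mark.parametrize("outcome", ["hip", "any_osteoporotic"])
@pytest.mark.parametrize("sex", ["female", "male"])
def test_risk_factor_directionality(coeffs, sex, outcome):
    """Risk rises with falls, prior fractures and age; falls with BMD;
    moves with weight in the direction of the transcribed coefficient."""
    base = dict(sex=sex, age=72, t_score=-1.5, weight=72.0)

    def risk(variant, **overrides):
        profile = RiskProfile(**{**base, **overrides})
        return predict_risk(profile, outcome, 10, variant, coeffs).probability

    assert risk("bmd", falls_12mo=2) > risk("bmd", falls_12mo=0)
    assert risk("bmd", prior_fractures=3) > risk("bmd", prior_fractures=0)
    for a_lo, a_hi in [(60, 70), (70, 85), (85, 95)]:
        assert risk("bmd", age=a_hi) > risk("bmd", age=a_lo)
    assert risk("bmd", t_score=-2.5) > risk("bmd", t_score=-0.5)
    sign = np.sign(coeffs.block(outcome, sex, "weight").weight_per_kg)
    assert np.sign(risk("weight", weight=90.0) - risk("weight", weight=55.0)) == sign


@settings(max_examples=40, deadline=None, derandomize=True)
@given(bmd=st.floats(0.45, 1.4), sex=st.sampled_from(["female", "male"]))
def test_tscore_bmd_equivalence(coeffs, bmd, sex):
    """Supplying the same measurement as BMD or T-score is indistinguishable."""
    ref = coeffs.tscore_reference[sex]
    t = ref.bmd_to_tscore(bmd)
    by_bmd = predict_risk(
        RiskProfile(sex=sex, age=74, femoral_neck_bmd=bmd), "hip", 10, "bmd", coeffs
    ).probability
    by_t = predict_risk(
        RiskProfile(sex=sex, age=74, t_score=t), "hip", 10, "bmd", coeffs
    ).probability
    assert abs(by_bmd - by_t) < 1e-9


def test_counts_above_top_category_clamp_down(coeffs):
    lo = RiskProfile(sex="female", age=70, t_score=-1.0, prior_fractures=3, falls_12mo=3)
    hi = RiskProfile(sex="female", age=70, t_score=-1.0, prior_fractures=9, falls_12mo=7)
    for outcome in ("hip", "any_osteoporotic"):
        assert (
            predict_risk(hi, outcome, 10, "bmd", coeffs).probability
            == predict_risk(lo, outcome, 10, "bmd", coeffs).probability
        )


def test_missing_predictor_and_horizon_errors(coeffs):
    no_bone = RiskProfile(sex="male", age=70, weight=80.0)
    with pytest.raises(MissingPredictorError):
        predict_risk(no_bone, "hip", 10, "bmd", coeffs)
    no_weight = RiskProfile(sex="male", age=70, t_score=-1.0)
    with pytest.raises(MissingPredictorError):
        predict_risk(no_weight, "hip", 10, "weight", coeffs)
    with pytest.raises(UnsupportedHorizonError):
        predict_risk(no_weight, "hip", 7, "bmd", coeffs)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(sex="other", age=70),
        dict(sex="female", age=40),
        dict(sex="female", age=115),
        dict(sex="female", age=70, femoral_neck_bmd=0.1),
        dict(sex="female", age=70, weight=20.0),
        dict(sex="female", age=70, prior_fractures=-1),
        dict(sex="female", age=70, falls_12mo=1.5),
        dict(sex="female", age=float("nan")),
    ],
)
def test_invalid_profiles_are_rejected(kwargs):
    with pytest.raises(ProfileError):
        RiskProfile(**kwargs)


def test_predict_cohort_matches_scalar_loop(coeffs, rng):
    profiles = [
        RiskProfile(
            sex=rng.choice(["female", "male"]),
            age=float(rng.uniform(60, 95)),
            t_score=float(rng.uniform(-3.5, 1.0)),
            weight=float(rng.uniform(45, 110)),
            prior_fractures=int(rng.integers(0, 5)),
            falls_12mo=int(rng.integers(0, 4)),
        )
        for _ in range(100)
    ]
    for outcome, variant in [("hip", "bmd"), ("any_osteoporotic", "weight")]:
        batch = predict_cohort(profiles, outcome, 10, variant, coeffs)
        assert len(batch) == 100
        for profile, est in zip(profiles, batch):
            assert est.probability == predict_risk(
                profile, outcome, 10, variant, coeffs
            ).probability


def test_predict_cohort_empty_and_error_naming(coeffs):
    assert predict_cohort([], "hip", 10, "bmd", coeffs) == []

    class Stub:
        subject_id = "T042"
        sex = "female"
        age = 70.0
        femoral_neck_bmd = None
        t_score = None
        weight = 70.0
        prior_fractures = 0
        falls_12mo = 0

    with pytest.raises(MissingPredictorError, match="T042"):
        predict_cohort([Stub()], "hip", 10, "bmd", coeffs)
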