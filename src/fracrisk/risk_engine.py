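"""Evaluate the absolute fracture-risk equations for profiles and cohorts.

A :class:`RiskProfile` carries one individual's predictors: sex, age,
femoral-neck BMD (or the equivalent T-score), body weight, the count of
low-trauma fractures since age 50 and the count of falls in the last 12
months.  :func:`predict_risk` combines a profile with a validated
coefficient set to produce the absolute probability of a hip or any
non-vertebral osteoporotic fracture over a 5- or 10-year horizon, for
either the BMD or the body-weight model variant.

Counts above the model's top category (3+ for both prior fractures and
falls) are clamped down to it — the equations define scores only for their
listed categories — and each clamp is reported through the module logger.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .coefficients import (
    GarvanCoefficients,
    HORIZONS,
    ModelBlock,
    N_COUNT_CATEGORIES,
    OUTCOMES,
    VARIANTS,
)
from .errors import (
    MissingPredictorError,
    ProfileError,
    UnsupportedHorizonError,
)

logger = logging.getLogger(__name__)

AGE_RANGE = (50.0, 110.0)
BMD_RANGE = (0.2, 2.0)     # g/cm^2, open interval
WEIGHT_RANGE = (25.0, 250.0)  # kg, open interval

# Probabilities are clipped to this open interval: with extreme (but valid)
# predictor values exp(eta) can be large enough that 1 - S0**exp(eta) rounds
# to 1.0 in float64, while the model's risks are strictly inside (0, 1).
_PROB_EPS = 1e-12


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ProfileError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class RiskProfile:
    """One individual's predictor vector.

    Parameters
    ----------
    sex : {"female", "male"}
    age : float
        Years; must lie in [50, 110].
    femoral_neck_bmd : float, optional
        Areal BMD in g/cm^2; interchangeable with `t_score` via the
        reference constants in the coefficient document.
    t_score : float, optional
        Femoral-neck BMD in young-adult standard deviations.
    weight : float, optional
        Body weight in kg (required by the weight variant).
    prior_fractures : int
        Low-trauma fractures since age 50 (clamped to 3+ at evaluation).
    falls_12mo : int
        Falls during the previous 12 months (clamped to 3+ at evaluation).
    """

    sex: str
    age: float
    femoral_neck_bmd: float | None = None
    t_score: float | None = None
    weight: float | None = None
    prior_fractures: int = 0
    falls_12mo: int = 0

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ProfileError(f"sex must be 'female' or 'male', got {self.sex!r}")
        age = _require_finite("age", self.age)
        if not AGE_RANGE[0] <= age <= AGE_RANGE[1]:
            raise ProfileError(
                f"age {age} outside the model's supported range {AGE_RANGE}"
            )
        if self.femoral_neck_bmd is not None:
            bmd = _require_finite("femoral_neck_bmd", self.femoral_neck_bmd)
            if not BMD_RANGE[0] < bmd < BMD_RANGE[1]:
                raise ProfileError(
                    f"femoral_neck_bmd {bmd} g/cm^2 outside plausible range {BMD_RANGE}"
                )
        if self.t_score is not None:
            _require_finite("t_score", self.t_score)
        if self.weight is not None:
            w = _require_finite("weight", self.weight)
            if not WEIGHT_RANGE[0] < w < WEIGHT_RANGE[1]:
                raise ProfileError(
                    f"weight {w} kg outside plausible range {WEIGHT_RANGE}"
                )
        for name in ("prior_fractures", "falls_12mo"):
            count = getattr(self, name)
            if not isinstance(count, (int, np.integer)) or isinstance(count, bool):
                raise ProfileError(f"{name} must be an integer count, got {count!r}")
            if count < 0:
                raise ProfileError(f"{name} must be >= 0, got {count}")


@dataclass(frozen=True)
class RiskEstimate:
    """Absolute fracture probability for one profile/outcome/horizon/variant."""

    probability: float
    horizon: int       # years
    outcome: str
    variant: str
    profile: RiskProfile


def clamp_count(count: int, label: str = "count") -> int:
    """Clamp a count to the model's top category (3+), logging the clamp."""
    top = N_COUNT_CATEGORIES - 1
    if count > top:
        logger.info("%s=%d clamped to model top category %d+", label, count, top)
        return top
    return int(count)


def _resolve_tscore(profile: RiskProfile, coefficients: GarvanCoefficients) -> float:
    if profile.femoral_neck_bmd is not None:
        ref = coefficients.tscore_reference[profile.sex]
        return ref.bmd_to_tscore(profile.femoral_neck_bmd)
    if profile.t_score is not None:
        return profile.t_score
    raise MissingPredictorError(
        "BMD variant requires femoral_neck_bmd or t_score; neither is present"
    )


def _risk_from_block(block: ModelBlock, horizon: int, eta) -> np.ndarray:
    """Vectorized 1 - S0(t)^exp(eta), clipped to the open unit interval."""
    log_s0 = math.log(block.baseline_survival[horizon])
    risk = -np.expm1(np.exp(np.asarray(eta, dtype=float)) * log_s0)
    return np.clip(risk, _PROB_EPS, 1.0 - _PROB_EPS)


def predict_risk(
    profile: RiskProfile,
    outcome: str,
    horizon: int,
    variant: str,
    coefficients: GarvanCoefficients,
) -> RiskEstimate:
    """Absolute fracture probability for one profile.

    Raises
    ------
    UnsupportedHorizonError
        For horizons other than 5 or 10 years (no interpolation).
    MissingPredictorError
        When the variant's predictor (BMD/T-score or weight) is absent.
    """
    if outcome not in OUTCOMES:
        raise ProfileError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    if variant not in VARIANTS:
        raise ProfileError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if horizon not in HORIZONS:
        raise UnsupportedHorizonError(
            f"horizon {horizon!r} is not defined by the model; use 5 or 10 years"
        )
    block = coefficients.block(outcome, profile.sex, variant)
    if variant == "bmd":
        measurement = _resolve_tscore(profile, coefficients)
    else:
        if profile.weight is None:
            raise MissingPredictorError("weight variant requires body weight")
        measurement = profile.weight
    eta = block.linear_predictor(
        profile.age,
        measurement,
        clamp_count(profile.prior_fractures, "prior_fractures"),
        clamp_count(profile.falls_12mo, "falls_12mo"),
    )
    probability = float(_risk_from_block(block, horizon, eta))
    return RiskEstimate(
        probability=probability,
        horizon=horizon,
        outcome=outcome,
        variant=variant,
        profile=profile,
    )


def predict_cohort(
    records: Iterable,
    outcome: str,
    horizon: int,
    variant: str,
    coefficients: GarvanCoefficients,
) -> list[RiskEstimate]:
    """Element-wise :func:`predict_risk` over cohort records, order preserving.

    Accepts :class:`RiskProfile` objects or any objects exposing the profile
    fields (e.g. :class:`fracrisk.cohort.CohortRecord`).  Any invalid record
    raises, naming the record; nothing is silently skipped.
    """
    estimates: list[RiskEstimate] = []
    for i, record in enumerate(records):
        try:
            profile = as_profile(record)
            estimates.append(predict_risk(profile, outcome, horizon, variant, coefficients))
        except Exception as exc:
            ident = getattr(record, "subject_id", f"index {i}")
            raise type(exc)(f"record {ident}: {exc}") from exc
    return estimates


def as_profile(record) -> RiskProfile:
    """Build a :class:`RiskProfile` from any record exposing profile fields."""
    if isinstance(record, RiskProfile):
        return record
    return RiskProfile(
        sex=record.sex,
        age=record.age,
        femoral_neck_bmd=getattr(record, "femoral_neck_bmd", None),
        t_score=getattr(record, "t_score", None),
        weight=getattr(record, "weight", None),
        prior_fractures=int(record.prior_fractures),
        falls_12mo=int(record.falls_12mo),
    )


def predict_array(
    block: ModelBlock,
    horizon: int,
    age: Sequence[float],
    measurement: Sequence[float],
    prior_fractures: Sequence[int],
    falls_12mo: Sequence[int],
) -> np.ndarray:
    """Vectorized risk evaluation on pre-validated arrays.

    `measurement` is T-scores for the BMD variant, kilograms for the weight
    variant; counts must already be clamped to [0, 3]. Shared by the cohort
    simulator and `validate`; scalar `predict_risk` is the reference path.
    """
    eta = block.linear_predictor(
        np.asarray(age, dtype=float),
        np.asarray(measurement, dtype=float),
        np.minimum(np.asarray(prior_fractures, dtype=int), N_COUNT_CATEGORIES - 1),
        np.minimum(np.asarray(falls_12mo, dtype=int), N_COUNT_CATEGORIES - 1),
    )
    return _risk_from_block(block, horizon, eta)
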