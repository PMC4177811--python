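"""Synthetic elderly-cohort generator with model-consistent ground truth.

The generator emulates a Norwegian-style population cohort of women and men
aged 60+ (the ``tromso_like.cfg`` defaults follow such a cohort's published
baseline distributions): sex-specific age, femoral-neck BMD (declining
linearly with age), body weight correlated with BMD, and categorical
prior-fracture and fall counts.

Event times are generated from the risk model itself so that calibration
holds by construction: each subject gets a constant fracture hazard
calibrated so the 10-year cumulative incidence equals their model-predicted
10-year any-osteoporotic risk (BMD variant).  Hip events are a thinned
subset of any-fracture events with subject-specific probability
``predicted hip risk / predicted any risk``.  An independent exponential
death time and fixed administrative censoring complete the follow-up:
observed time is the minimum of fracture, death and censoring times.

A single :class:`numpy.random.Generator` seeded from the config drives all
draws; identical configs produce identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .coefficients import GarvanCoefficients
from .cohort import CohortRecord
from .errors import ConfigError, DomainError
from .risk_engine import predict_array

DEFAULT_CONFIG_PATH = resources.files("fracrisk.data") / "tromso_like.cfg"


@dataclass(frozen=True)
class NormalSpec:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigError(f"sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class BMDSpec(NormalSpec):
    age_slope_per_year: float = 0.0  # g/cm^2 per year, mean anchored at age 70


def _probs(name: str, probs: Sequence[float]) -> tuple[float, ...]:
    p = tuple(float(x) for x in probs)
    if any(x < 0 for x in p) or not math.isclose(sum(p), 1.0, abs_tol=1e-9):
        raise ConfigError(f"{name} probabilities must be >= 0 and sum to 1, got {p}")
    return p


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Distributional targets and censoring mechanism for one cohort draw."""

    n: int
    seed: int
    sex_fraction_female: float
    age: Mapping[str, NormalSpec]          # per sex; truncated to age_range
    bmd: Mapping[str, BMDSpec]             # per sex, g/cm^2
    weight: Mapping[str, NormalSpec]       # per sex, kg
    weight_bmd_correlation: float
    prior_fracture_probs: Mapping[str, tuple[float, ...]]  # categories 0..3+
    falls_probs: Mapping[str, tuple[float, ...]]           # categories 0..2+
    mortality_rate: float = 0.0            # deaths per person-year
    admin_censor_years: float = 10.0
    noise_sd_weight_channel: float = 0.4   # log-odds SD for degrade_predictions
    age_range: tuple[float, float] = (60.0, 90.0)

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ConfigError("sex_fraction_female must lie in [0, 1]")
        if self.mortality_rate < 0:
            raise ConfigError("mortality_rate must be >= 0")
        if self.admin_censor_years <= 0:
            raise ConfigError("admin_censor_years must be > 0")
        if self.noise_sd_weight_channel < 0:
            raise ConfigError("noise_sd_weight_channel must be >= 0")
        for sex in ("female", "male"):
            for section in ("age", "bmd", "weight", "prior_fracture_probs", "falls_probs"):
                if sex not in getattr(self, section):
                    raise ConfigError(f"{section} lacks an entry for {sex}")
            _probs(f"prior_fracture_probs[{sex}]", self.prior_fracture_probs[sex])
            _probs(f"falls_probs[{sex}]", self.falls_probs[sex])


def load_config(path: str | Path | None = None, **overrides) -> SyntheticCohortConfig:
    """Read a YAML cohort config (the shipped Table-1-like file by default).

    Keyword overrides replace top-level scalar fields, e.g.
    ``load_config(n=20000, seed=7, mortality_rate=0.0)``.
    """
    text = (DEFAULT_CONFIG_PATH if path is None else Path(path)).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config does not parse: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigError("config must be a mapping")

    def norm(section, cls=NormalSpec):
        return {sex: cls(**doc[section][sex]) for sex in ("female", "male")}

    try:
        cfg = dict(
            n=int(doc["n"]),
            seed=int(doc["seed"]),
            sex_fraction_female=float(doc["sex_fraction_female"]),
            age=norm("age"),
            bmd=norm("bmd", BMDSpec),
            weight=norm("weight"),
            weight_bmd_correlation=float(doc["weight_bmd_correlation"]),
            prior_fracture_probs={
                sex: _probs(f"prior_fracture_probs[{sex}]", doc["prior_fracture_probs"][sex])
                for sex in ("female", "male")
            },
            falls_probs={
                sex: _probs(f"falls_probs[{sex}]", doc["falls_probs"][sex])
                for sex in ("female", "male")
            },
            mortality_rate=float(doc.get("mortality_rate", 0.0)),
            admin_censor_years=float(doc.get("admin_censor_years", 10.0)),
            noise_sd_weight_channel=float(doc.get("noise_sd_weight_channel", 0.4)),
            age_range=tuple(doc.get("age_range", (60.0, 90.0))),
        )
    except KeyError as exc:
        raise ConfigError(f"config lacks required field {exc}") from exc
    cfg.update(overrides)
    return SyntheticCohortConfig(**cfg)


def _truncnorm(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    config: SyntheticCohortConfig, coefficients: GarvanCoefficients
) -> list[CohortRecord]:
    """Draw a cohort whose fracture times follow the model's own predictions."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    sexes = np.where(rng.random(n) < config.sex_fraction_female, "female", "male")

    age = np.empty(n)
    bmd = np.empty(n)
    weight = np.empty(n)
    fx = np.zeros(n, dtype=int)
    falls = np.zeros(n, dtype=int)
    lo, hi = config.age_range
    for sex in ("female", "male"):
        m = sexes == sex
        k = int(m.sum())
        if k == 0:
            continue
        aspec = config.age[sex]
        age[m] = _truncnorm(rng, aspec.mean, aspec.sd, lo, hi, k)
        bspec = config.bmd[sex]
        z_bmd = rng.standard_normal(k)
        bmd_mean = bspec.mean + bspec.age_slope_per_year * (age[m] - 70.0)
        bmd[m] = np.clip(bmd_mean + bspec.sd * z_bmd, 0.4, 1.6)
        wspec = config.weight[sex]
        rho = config.weight_bmd_correlation
        z_w = rho * z_bmd + math.sqrt(max(1 - rho**2, 0.0)) * rng.standard_normal(k)
        weight[m] = np.clip(wspec.mean + wspec.sd * z_w, 35.0, 150.0)
        fx[m] = rng.choice(
            len(config.prior_fracture_probs[sex]), size=k, p=config.prior_fracture_probs[sex]
        )
        falls[m] = rng.choice(len(config.falls_probs[sex]), size=k, p=config.falls_probs[sex])

    # model-consistent event process (BMD variant is the data-generating truth)
    p_any10 = np.empty(n)
    p_hip10 = np.empty(n)
    for sex in ("female", "male"):
        m = sexes == sex
        if not m.any():
            continue
        ref = coefficients.tscore_reference[sex]
        tscores = ref.bmd_to_tscore(bmd[m])
        p_any10[m] = predict_array(
            coefficients.block("any_osteoporotic", sex, "bmd"), 10,
            age[m], tscores, fx[m], falls[m],
        )
        p_hip10[m] = predict_array(
            coefficients.block("hip", sex, "bmd"), 10,
            age[m], tscores, fx[m], falls[m],
        )

    hazard = -np.log1p(-p_any10) / 10.0
    t_frac = rng.exponential(1.0 / hazard)
    is_hip = rng.random(n) < np.clip(p_hip10 / p_any10, 0.0, 1.0)
    if config.mortality_rate > 0:
        t_death = rng.exponential(1.0 / config.mortality_rate, size=n)
    else:
        t_death = np.full(n, np.inf)
    t_admin = config.admin_censor_years

    t_free = np.minimum(t_death, t_admin)        # fracture-free follow-up end
    any_event = (t_frac <= t_free).astype(int)
    any_time = np.where(any_event == 1, t_frac, t_free)
    hip_event = ((any_event == 1) & is_hip).astype(int)
    hip_time = np.where(hip_event == 1, t_frac, t_free)
    died = ((t_death < t_admin) & (any_event == 0)).astype(int)
    # follow-up strictly positive even if a draw lands at exactly 0
    any_time = np.maximum(any_time, 1e-9)
    hip_time = np.maximum(hip_time, 1e-9)

    width = len(str(n))
    return [
        CohortRecord(
            subject_id=f"S{i + 1:0{width}d}",
            sex=str(sexes[i]),
            age=float(age[i]),
            femoral_neck_bmd=float(bmd[i]),
            t_score=None,
            weight=float(weight[i]),
            prior_fractures=int(fx[i]),
            falls_12mo=int(falls[i]),
            any_event=int(any_event[i]),
            any_followup_years=float(any_time[i]),
            hip_event=int(hip_event[i]),
            hip_followup_years=float(hip_time[i]),
            died=int(died[i]),
        )
        for i in range(n)
    ]


def degrade_predictions(predicted, noise_sd: float, seed: int | np.random.Generator):
    """Perturb predictions with log-scale Gaussian noise, renormalized to (0,1).

    Each probability p becomes ``p*e^eps / (p*e^eps + (1-p))`` with
    ``eps ~ N(0, noise_sd^2)`` — a Gaussian shift of log p renormalized
    against the complementary mass, so ``noise_sd=0`` is the identity and
    outputs stay strictly inside (0, 1).  Used to build a weaker "weight
    channel" comparator with a controlled information loss.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    p = np.asarray(predicted, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise DomainError("predictions must lie strictly inside (0, 1)")
    if noise_sd == 0:
        return p.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=p.shape)
    q = p * np.exp(eps)
    return q / (q + (1.0 - p))
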