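"""Load, validate and serialize the fracture-risk model coefficients.

The risk engine is a set of Cox-type absolute-risk equations: for each
combination of outcome (hip, any non-vertebral osteoporotic fracture), sex
and predictor variant (femoral-neck BMD or body weight) a linear predictor
``eta`` is combined with a fixed baseline survival ``S0(t)`` at the 5- and
10-year horizons:

    risk(t) = 1 - S0(t) ** exp(eta)

Coefficients ship as a human-readable, versioned YAML document
(:data:`DEFAULT_COEFFICIENT_PATH`) so the transcription is auditable and
diff-able; :func:`load_coefficients` validates completeness and every
numeric field before anything is evaluated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import CoefficientSpecError, IncompleteCoefficientsError

OUTCOMES = ("hip", "any_osteoporotic")
SEXES = ("female", "male")
VARIANTS = ("bmd", "weight")
HORIZONS = (5, 10)

#: Number of predictor categories (0, 1, 2, 3+) for counts.
N_COUNT_CATEGORIES = 4

DEFAULT_COEFFICIENT_PATH = resources.files("fracrisk.data") / "garvan_coefficients.yaml"


@dataclass(frozen=True)
class TScoreReference:
    """Young-adult femoral-neck reference used to map BMD to a T-score."""

    young_adult_mean: float  # g/cm^2
    young_adult_sd: float    # g/cm^2

    def bmd_to_tscore(self, bmd: float) -> float:
        return (bmd - self.young_adult_mean) / self.young_adult_sd

    def tscore_to_bmd(self, tscore: float) -> float:
        return self.young_adult_mean + tscore * self.young_adult_sd


@dataclass(frozen=True)
class ModelBlock:
    """Coefficients for one (outcome, sex, variant) equation."""

    outcome: str
    sex: str
    variant: str
    age_per_year: float
    age_center: float
    prior_fracture_scores: tuple[float, ...]
    falls_scores: tuple[float, ...]
    baseline_survival: Mapping[int, float]  # horizon (years) -> S0
    # exactly one of the following pairs is populated, per variant
    tscore_per_sd: float | None = None
    tscore_center: float | None = None
    weight_per_kg: float | None = None
    weight_center: float | None = None

    def linear_predictor(self, age, measurement, prior_fractures, falls):
        """Evaluate eta; `measurement` is a T-score or weight per variant.

        Accepts scalars or numpy arrays (counts must already be clamped to
        the model's top category).
        """
        eta = self.age_per_year * (age - self.age_center)
        if self.variant == "bmd":
            eta = eta + self.tscore_per_sd * (measurement - self.tscore_center)
        else:
            eta = eta + self.weight_per_kg * (measurement - self.weight_center)
        fx = np.asarray(self.prior_fracture_scores)[np.asarray(prior_fractures)]
        fl = np.asarray(self.falls_scores)[np.asarray(falls)]
        return eta + fx + fl


@dataclass(frozen=True)
class GarvanCoefficients:
    """Complete, validated coefficient set for all model blocks."""

    version: str
    source: str
    tscore_reference: Mapping[str, TScoreReference]
    blocks: Mapping[tuple[str, str, str], ModelBlock] = field(repr=False)

    def block(self, outcome: str, sex: str, variant: str) -> ModelBlock:
        try:
            return self.blocks[(outcome, sex, variant)]
        except KeyError:
            raise IncompleteCoefficientsError(
                f"no coefficient block for {sex} {_short(outcome)} {variant}"
            ) from None


def _short(outcome: str) -> str:
    return "any" if outcome == "any_osteoporotic" else outcome


def _number(block_name: str, mapping: Mapping, key: str) -> float:
    if key not in mapping:
        raise IncompleteCoefficientsError(f"block {block_name}: missing field {key!r}")
    value = mapping[key]
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise CoefficientSpecError(
            f"block {block_name}: field {key!r} is not a number ({value!r})"
        )
    return float(value)


def _scores(block_name: str, mapping: Mapping, key: str) -> tuple[float, ...]:
    if key not in mapping:
        raise IncompleteCoefficientsError(f"block {block_name}: missing field {key!r}")
    raw = mapping[key]
    if not isinstance(raw, (list, tuple)) or len(raw) != N_COUNT_CATEGORIES:
        raise CoefficientSpecError(
            f"block {block_name}: {key!r} must list {N_COUNT_CATEGORIES} category scores"
        )
    out = []
    for i, v in enumerate(raw):
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            raise CoefficientSpecError(
                f"block {block_name}: {key}[{i}] is not a number ({v!r})"
            )
        out.append(float(v))
    return tuple(out)


def _parse_block(outcome: str, sex: str, variant: str, raw: Mapping) -> ModelBlock:
    name = f"{sex} {_short(outcome)} {variant}"
    base_raw = raw.get("baseline_survival")
    if not isinstance(base_raw, Mapping):
        raise IncompleteCoefficientsError(f"block {name}: missing baseline_survival map")
    baseline: dict[int, float] = {}
    for horizon in HORIZONS:
        if horizon not in base_raw and str(horizon) not in base_raw:
            raise IncompleteCoefficientsError(
                f"block {name}: missing baseline_survival for horizon {horizon}"
            )
        value = base_raw.get(horizon, base_raw.get(str(horizon)))
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise CoefficientSpecError(
                f"block {name}: baseline_survival[{horizon}] is not a number ({value!r})"
            )
        if not 0.0 < float(value) < 1.0:
            raise CoefficientSpecError(
                f"block {name}: baseline_survival[{horizon}] must lie in (0, 1)"
            )
        baseline[horizon] = float(value)
    if baseline[10] > baseline[5]:
        raise CoefficientSpecError(
            f"block {name}: 10-year baseline survival exceeds the 5-year value"
        )

    kwargs = dict(
        outcome=outcome,
        sex=sex,
        variant=variant,
        age_per_year=_number(name, raw, "age_per_year"),
        age_center=_number(name, raw, "age_center"),
        prior_fracture_scores=_scores(name, raw, "prior_fracture_scores"),
        falls_scores=_scores(name, raw, "falls_scores"),
        baseline_survival=baseline,
    )
    if variant == "bmd":
        kwargs["tscore_per_sd"] = _number(name, raw, "tscore_per_sd")
        kwargs["tscore_center"] = _number(name, raw, "tscore_center")
    else:
        kwargs["weight_per_kg"] = _number(name, raw, "weight_per_kg")
        kwargs["weight_center"] = _number(name, raw, "weight_center")
    return ModelBlock(**kwargs)


def load_coefficients(spec_document: str | Path | io.IOBase | None = None) -> GarvanCoefficients:
    """Parse and validate a coefficient document.

    Parameters
    ----------
    spec_document
        Path to a YAML coefficient file, an open text stream, or a YAML
        string. ``None`` loads the coefficient set shipped with the package.

    Raises
    ------
    IncompleteCoefficientsError
        If any (outcome, sex, variant, horizon) block or field is missing;
        the message names the block.
    CoefficientSpecError
        On unparseable YAML or a malformed numeric field.
    """
    if spec_document is None:
        text = DEFAULT_COEFFICIENT_PATH.read_text()
    elif isinstance(spec_document, Path):
        text = spec_document.read_text()
    elif isinstance(spec_document, str):
        # Treat as a path when one exists, else as document text.
        try:
            is_path = Path(spec_document).exists()
        except (OSError, ValueError):  # e.g. embedded newlines in YAML text
            is_path = False
        text = Path(spec_document).read_text() if is_path else spec_document
    else:
        text = spec_document.read()

    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise CoefficientSpecError(f"coefficient document does not parse: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise CoefficientSpecError("coefficient document is not a mapping")
    if "version" not in doc or not str(doc["version"]).strip():
        raise CoefficientSpecError("coefficient document must declare a version string")

    ref_raw = doc.get("tscore_reference")
    if not isinstance(ref_raw, Mapping):
        raise IncompleteCoefficientsError("missing tscore_reference section")
    references = {}
    for sex in SEXES:
        if sex not in ref_raw:
            raise IncompleteCoefficientsError(f"missing tscore_reference for {sex}")
        r = ref_raw[sex]
        mean = _number(f"tscore_reference {sex}", r, "young_adult_mean")
        sd = _number(f"tscore_reference {sex}", r, "young_adult_sd")
        if sd <= 0:
            raise CoefficientSpecError(f"tscore_reference {sex}: young_adult_sd must be > 0")
        references[sex] = TScoreReference(mean, sd)

    models = doc.get("models")
    if not isinstance(models, Mapping):
        raise IncompleteCoefficientsError("missing models section")
    blocks: dict[tuple[str, str, str], ModelBlock] = {}
    for outcome in OUTCOMES:
        for sex in SEXES:
            for variant in VARIANTS:
                raw = models.get(outcome, {}).get(sex, {}).get(variant)
                if not isinstance(raw, Mapping):
                    raise IncompleteCoefficientsError(
                        f"missing coefficient block: {sex} {_short(outcome)} {variant}"
                    )
                blocks[(outcome, sex, variant)] = _parse_block(outcome, sex, variant, raw)

    return GarvanCoefficients(
        version=str(doc["version"]),
        source=str(doc.get("source", "")),
        tscore_reference=references,
        blocks=blocks,
    )


def dump_coefficients(coefficients: GarvanCoefficients) -> str:
    """Serialize a coefficient set back to YAML (round-trips with load)."""
    doc: dict = {
        "version": coefficients.version,
        "source": coefficients.source,
        "tscore_reference": {
            sex: {
                "young_adult_mean": ref.young_adult_mean,
                "young_adult_sd": ref.young_adult_sd,
            }
            for sex, ref in coefficients.tscore_reference.items()
        },
        "models": {},
    }
    for (outcome, sex, variant), b in coefficients.blocks.items():
        block_doc: dict = {
            "age_per_year": b.age_per_year,
            "age_center": b.age_center,
            "prior_fracture_scores": list(b.prior_fracture_scores),
            "falls_scores": list(b.falls_scores),
            "baseline_survival": dict(b.baseline_survival),
        }
        if variant == "bmd":
            block_doc["tscore_per_sd"] = b.tscore_per_sd
            block_doc["tscore_center"] = b.tscore_center
        else:
            block_doc["weight_per_kg"] = b.weight_per_kg
            block_doc["weight_center"] = b.weight_center
        doc["models"].setdefault(outcome, {}).setdefault(sex, {})[variant] = block_doc
    return yaml.safe_dump(doc, sort_keys=False)
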