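"""Cohort tables, follow-up summaries and incidence rates.

A cohort is a delimited-text table with one row per subject carrying the
risk-profile fields plus, for each outcome (hip, any non-vertebral
osteoporotic fracture), a first-event indicator and the follow-up time in
years to that first event or to censoring (migration, death or the end of
the registration window).  Follow-up is tracked separately per outcome
because censoring at the first fracture differs between the hip and
any-fracture analyses.

Incidence is events per 1000 person-years; confidence intervals default to
the exact Poisson (gamma-quantile) method, which behaves correctly at small
counts, with a log-normal approximation as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DomainError,
    EmptyCohortError,
    RecordValidationError,
    SchemaError,
)

#: Canonical column names; a schema config maps these to the file's columns.
STANDARD_COLUMNS = (
    "subject_id",
    "sex",
    "age",
    "femoral_neck_bmd",
    "t_score",
    "weight",
    "prior_fractures",
    "falls_12mo",
    "any_event",
    "any_followup_years",
    "hip_event",
    "hip_followup_years",
    "died",
)

#: Predictor columns that may be blank in the file (rejected later, per
#: variant, at prediction time — mirroring upstream exclusion of subjects
#: with missing predictors rather than hard-failing the whole read).
_OPTIONAL_COLUMNS = ("femoral_neck_bmd", "t_score", "weight")

OUTCOME_FIELDS = {
    "hip": ("hip_event", "hip_followup_years"),
    "any_osteoporotic": ("any_event", "any_followup_years"),
}
_OUTCOME_ALIASES = {"any": "any_osteoporotic", "osteoporotic": "any_osteoporotic"}


def canonical_outcome(outcome: str) -> str:
    outcome = _OUTCOME_ALIASES.get(outcome, outcome)
    if outcome not in OUTCOME_FIELDS:
        raise DomainError(
            f"unknown outcome {outcome!r}; expected 'hip' or 'any_osteoporotic'"
        )
    return outcome


@dataclass(frozen=True)
class CohortRecord:
    """One subject: predictors plus per-outcome follow-up and vital status."""

    subject_id: str
    sex: str
    age: float
    femoral_neck_bmd: float | None
    t_score: float | None
    weight: float | None
    prior_fractures: int
    falls_12mo: int
    any_event: int
    any_followup_years: float
    hip_event: int
    hip_followup_years: float
    died: int

    def __post_init__(self):
        sid = self.subject_id
        if self.sex not in ("female", "male"):
            raise RecordValidationError(sid, f"sex must be female/male, got {self.sex!r}")
        for name in ("any_followup_years", "hip_followup_years"):
            t = getattr(self, name)
            if not (isinstance(t, (int, float)) and math.isfinite(t)) or t <= 0:
                raise RecordValidationError(sid, f"{name} must be > 0, got {t!r}")
        for name in ("any_event", "hip_event", "died"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise RecordValidationError(sid, f"{name} must be 0 or 1, got {v!r}")
        for name in ("prior_fractures", "falls_12mo"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise RecordValidationError(sid, f"{name} must be a count >= 0, got {v!r}")


@dataclass(frozen=True)
class FollowUpSummary:
    n_subjects: int
    n_events: int
    person_years: float


@dataclass(frozen=True)
class IncidenceRate:
    """First incident fractures per 1000 person-years with a 95% CI."""

    rate: float
    ci_low: float
    ci_high: float
    method: str


_SEX_CODES = {"female": "female", "f": "female", "male": "male", "m": "male"}


def _cell_float(sid: str, name: str, value, optional: bool = False) -> float | None:
    if pd.isna(value) or (isinstance(value, str) and not value.strip()):
        if optional:
            return None
        raise RecordValidationError(sid, f"missing value in column {name!r}")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RecordValidationError(sid, f"unparseable number {value!r} in column {name!r}")


def _cell_int(sid: str, name: str, value) -> int:
    v = _cell_float(sid, name, value)
    if v != int(v):
        raise RecordValidationError(sid, f"column {name!r} must be an integer, got {value!r}")
    return int(v)


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    sep: str = ",",
) -> list[CohortRecord]:
    """Read and validate a delimited-text cohort table.

    Parameters
    ----------
    path : str or file-like
        Comma-separated by default, header row required, UTF-8, period
        decimal mark.
    schema : mapping, optional
        Maps the canonical column names in :data:`STANDARD_COLUMNS` to the
        file's column names; identity by default.
    """
    schema = dict(schema or {})
    colmap = {std: schema.get(std, std) for std in STANDARD_COLUMNS}
    frame = pd.read_csv(path, sep=sep, dtype={colmap["subject_id"]: str})
    missing = [col for std, col in colmap.items() if col not in frame.columns]
    if missing:
        raise SchemaError(f"cohort file lacks mapped column(s): {', '.join(missing)}")

    records: list[CohortRecord] = []
    for _, row in frame.iterrows():
        sid = str(row[colmap["subject_id"]])
        sex_raw = str(row[colmap["sex"]]).strip().lower()
        if sex_raw not in _SEX_CODES:
            raise RecordValidationError(sid, f"unrecognized sex code {row[colmap['sex']]!r}")
        records.append(
            CohortRecord(
                subject_id=sid,
                sex=_SEX_CODES[sex_raw],
                age=_cell_float(sid, "age", row[colmap["age"]]),
                femoral_neck_bmd=_cell_float(
                    sid, "femoral_neck_bmd", row[colmap["femoral_neck_bmd"]], optional=True
                ),
                t_score=_cell_float(sid, "t_score", row[colmap["t_score"]], optional=True),
                weight=_cell_float(sid, "weight", row[colmap["weight"]], optional=True),
                prior_fractures=_cell_int(sid, "prior_fractures", row[colmap["prior_fractures"]]),
                falls_12mo=_cell_int(sid, "falls_12mo", row[colmap["falls_12mo"]]),
                any_event=_cell_int(sid, "any_event", row[colmap["any_event"]]),
                any_followup_years=_cell_float(
                    sid, "any_followup_years", row[colmap["any_followup_years"]]
                ),
                hip_event=_cell_int(sid, "hip_event", row[colmap["hip_event"]]),
                hip_followup_years=_cell_float(
                    sid, "hip_followup_years", row[colmap["hip_followup_years"]]
                ),
                died=_cell_int(sid, "died", row[colmap["died"]]),
            )
        )
    return records


def cohort_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Cohort records as a DataFrame in the standard column order."""
    return pd.DataFrame([vars(r) for r in records], columns=list(STANDARD_COLUMNS))


def write_cohort(records: Sequence[CohortRecord], path, sep: str = ",") -> None:
    cohort_frame(records).to_csv(path, sep=sep, index=False)


def summarize_followup(records: Sequence[CohortRecord], outcome: str) -> FollowUpSummary:
    """Subjects, first incident fractures and person-years for one outcome."""
    outcome = canonical_outcome(outcome)
    if len(records) == 0:
        raise EmptyCohortError("cannot summarize an empty cohort")
    event_field, time_field = OUTCOME_FIELDS[outcome]
    n_events = sum(getattr(r, event_field) for r in records)
    person_years = float(sum(getattr(r, time_field) for r in records))
    return FollowUpSummary(
        n_subjects=len(records), n_events=int(n_events), person_years=person_years
    )


def incidence_rate(
    summary: FollowUpSummary,
    ci_method: str = "exact_poisson",
    alpha: float = 0.05,
) -> IncidenceRate:
    """Events per 1000 person-years with a Poisson confidence interval.

    ``exact_poisson`` uses the gamma/chi-square quantile bounds (lower bound
    0 when there are no events); ``lognormal`` uses the normal approximation
    on the log-rate scale and requires at least one event.
    """
    if summary.person_years <= 0:
        raise DomainError("person_years must be > 0 to form a rate")
    k = summary.n_events
    py = summary.person_years
    rate = 1000.0 * k / py
    if ci_method == "exact_poisson":
        low = 0.0 if k == 0 else 1000.0 * stats.chi2.ppf(alpha / 2, 2 * k) / (2 * py)
        high = 1000.0 * stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / (2 * py)
    elif ci_method == "lognormal":
        if k == 0:
            raise DomainError("log-normal CI undefined with zero events; use exact_poisson")
        z = stats.norm.ppf(1 - alpha / 2)
        se_log = 1.0 / math.sqrt(k)
        low = rate * math.exp(-z * se_log)
        high = rate * math.exp(z * se_log)
    else:
        raise DomainError(f"unknown ci_method {ci_method!r}")
    return IncidenceRate(rate=rate, ci_low=low, ci_high=high, method=ci_method)


def missing_predictor_filter(
    records: Iterable[CohortRecord], variant: str
) -> tuple[list[CohortRecord], int]:
    """Split off records lacking the predictor the variant needs.

    Mirrors the upstream exclusion of subjects with missing predictor data:
    returns (kept records, number excluded).
    """
    kept: list[CohortRecord] = []
    n_excluded = 0
    for r in records:
        if variant == "bmd":
            ok = r.femoral_neck_bmd is not None or r.t_score is not None
        elif variant == "weight":
            ok = r.weight is not None
        else:
            raise DomainError(f"unknown variant {variant!r}")
        if ok:
            kept.append(r)
        else:
            n_excluded += 1
    return kept, n_excluded
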