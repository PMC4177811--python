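"""Cohort IO, follow-up summaries, incidence rates and their invariants."""

import io

import numpy as np
import pytest
from scipy import stats

from fracrisk.cohort import (
    CohortRecord,
    FollowUpSummary,
    cohort_frame,
    incidence_rate,
    missing_predictor_filter,
    read_cohort,
    summarize_followup,
    write_cohort,
)
from fracrisk.errors import (
    DomainError,
    EmptyCohortError,
    RecordValidationError,
    SchemaError,
)

HEADER = (
    "subject_id,sex,age,femoral_neck_bmd,t_score,weight,prior_fractures,"
    "falls_12mo,any_event,any_followup_years,hip_event,hip_followup_years,died"
)


def _file(*rows):
    return io.StringIO("\n".join([HEADER, *rows]))


def _record(sid="S1", **overrides):
    base = dict(
        subject_id=sid, sex="female", age=70.0, femoral_neck_bmd=0.8,
        t_score=None, weight=70.0, prior_fractures=0, falls_12mo=0,
        any_event=0, any_followup_years=6.9, hip_event=0,
        hip_followup_years=6.9, died=0,
    )
    base.update(overrides)
    return CohortRecord(**base)


def test_read_well_formed_file():
    records = read_cohort(_file(
        "A,F,70,0.83,,69,0,0,1,3.2,0,8.0,0",
        "B,male,65,,-1.2,81,1,2,0,8.2,0,8.2,0",
        "C,F,75,0.71,,,3,1,1,1.5,1,1.5,0",
    ))
    assert len(records) == 3
    assert records[0].sex == "female" and records[1].sex == "male"
    assert records[1].t_score == -1.2 and records[1].femoral_neck_bmd is None
    assert records[2].weight is None  # missing predictors allowed at read time


def test_schema_mapping_and_missing_column():
    text = HEADER.replace("falls_12mo", "n_falls")
    records = read_cohort(
        io.StringIO(text + "\nA,F,70,0.83,,69,0,2,0,5.0,0,5.0,0"),
        schema={"falls_12mo": "n_falls"},
    )
    assert records[0].falls_12mo == 2
    with pytest.raises(SchemaError, match="falls_12mo"):
        read_cohort(io.StringIO(text + "\nA,F,70,0.83,,69,0,2,0,5.0,0,5.0,0"))


def test_row_level_validation_names_subject():
    with pytest.raises(RecordValidationError, match="BAD1"):
        read_cohort(_file("BAD1,F,70,0.83,,69,0,0,0,-1.0,0,5.0,0"))
    with pytest.raises(RecordValidationError, match="BAD2"):
        read_cohort(_file("BAD2,F,70,0.83,,69,zero,0,0,5.0,0,5.0,0"))


def test_round_trip_write_read(tmp_path):
    records = [_record("A"), _record("B", sex="male", any_event=1, any_followup_years=2.5)]
    path = tmp_path / "cohort.csv"
    write_cohort(records, path)
    again = read_cohort(path)
    assert again == records


def test_summarize_single_record():
    summary = summarize_followup([_record(any_followup_years=2.5)], "any_osteoporotic")
    assert summary == FollowUpSummary(n_subjects=1, n_events=0, person_years=2.5)


def test_summarize_mixed_events_hand_tally():
    records = [
        _record("A", any_event=1, any_followup_years=1.0, hip_event=1, hip_followup_years=1.0),
        _record("B", any_event=0, any_followup_years=8.0),
        _record("C", any_event=1, any_followup_years=4.5, hip_followup_years=8.0),
        _record("D", any_event=0, any_followup_years=2.0, died=1, hip_followup_years=2.0),
        _record("E", any_event=1, any_followup_years=7.0, hip_followup_years=8.0),
    ]
    any_summary = summarize_followup(records, "any")
    assert any_summary.n_events == 3
    assert any_summary.person_years == pytest.approx(1.0 + 8.0 + 4.5 + 2.0 + 7.0)
    hip_summary = summarize_followup(records, "hip")
    assert hip_summary.n_events == 1
    assert hip_summary.person_years == pytest.approx(1.0 + 6.9 + 8.0 + 2.0 + 8.0)
    with pytest.raises(EmptyCohortError):
        summarize_followup([], "hip")


def test_cohort_level_person_years_from_mean_followup():
    """1637 subjects followed a mean 6.9 years accrue 11,295.3 person-years."""
    records = [_record(f"W{i}", any_followup_years=6.9) for i in range(1637)]
    summary = summarize_followup(records, "any")
    assert summary.person_years == pytest.approx(11295.3)


@pytest.mark.parametrize(
    "events,person_years,expected",
    [(356, 1637 * 6.9, 31.5), (117, 1355 * 7.1, 12.2)],
)
def test_incidence_rate_printed_precision(events, person_years, expected):
    rate = incidence_rate(FollowUpSummary(2000, events, person_years))
    assert round(rate.rate, 1) == expected
    assert rate.ci_low <= rate.rate <= rate.ci_high


def test_zero_event_exact_poisson_upper_bound():
    rate = incidence_rate(FollowUpSummary(50, 0, 100.0))
    assert rate.rate == 0.0 and rate.ci_low == 0.0
    # closed form: chi2.ppf(0.975, 2)/2 = -ln(0.025) = 3.6889
    assert rate.ci_high == pytest.approx(1000 * 3.68888 / 100, rel=1e-4)


def test_lognormal_ci_and_domain_errors():
    summary = FollowUpSummary(100, 25, 500.0)
    exact = incidence_rate(summary)
    approx = incidence_rate(summary, ci_method="lognormal")
    assert approx.ci_low == pytest.approx(exact.ci_low, rel=0.1)
    assert approx.ci_high == pytest.approx(exact.ci_high, rel=0.1)
    with pytest.raises(DomainError):
        incidence_rate(FollowUpSummary(10, 0, 100.0), ci_method="lognormal")
    with pytest.raises(DomainError):
        incidence_rate(FollowUpSummary(0, 0, 0.0))
    with pytest.raises(DomainError):
        incidence_rate(summary, ci_method="wilson")


def test_summary_additivity_over_strata(rng):
    records = [
        _record(
            f"S{i}",
            any_event=int(rng.integers(0, 2)),
            any_followup_years=float(rng.uniform(0.5, 10)),
        )
        for i in range(60)
    ]
    whole = summarize_followup(records, "any")
    split = rng.integers(0, 3, size=60)
    parts = [
        summarize_followup([r for r, s in zip(records, split) if s == k], "any")
        for k in range(3)
    ]
    assert sum(p.n_subjects for p in parts) == whole.n_subjects
    assert sum(p.n_events for p in parts) == whole.n_events
    assert sum(p.person_years for p in parts) == pytest.approx(whole.person_years)


def test_rate_order_invariance_and_time_scaling(rng):
    records = [
        _record(
            f"S{i}",
            any_event=int(rng.integers(0, 2)),
            any_followup_years=float(rng.uniform(0.5, 10)),
        )
        for i in range(40)
    ]
    shuffled = list(records)
    rng.shuffle(shuffled)
    r1 = incidence_rate(summarize_followup(records, "any"))
    r2 = incidence_rate(summarize_followup(shuffled, "any"))
    assert r1.rate == pytest.approx(r2.rate)
    scaled = [
        _record(r.subject_id, any_event=r.any_event,
                any_followup_years=3.0 * r.any_followup_years)
        for r in records
    ]
    r3 = incidence_rate(summarize_followup(scaled, "any"))
    assert r3.rate == pytest.approx(r1.rate / 3.0)


def test_exact_ci_narrows_with_person_years():
    widths = []
    for py in (100.0, 1000.0, 10000.0):
        k = int(0.02 * py)  # fixed underlying rate of 20 per 1000 py
        r = incidence_rate(FollowUpSummary(1000, k, py))
        assert r.ci_low <= r.rate <= r.ci_high
        widths.append(r.ci_high - r.ci_low)
    assert widths[0] > widths[1] > widths[2]


def test_missing_predictor_filter_counts():
    records = [
        _record("A"),
        _record("B", femoral_neck_bmd=None),
        _record("C", femoral_neck_bmd=None, t_score=-1.5),
        _record("D", weight=None),
    ]
    kept, excluded = missing_predictor_filter(records, "bmd")
    assert [r.subject_id for r in kept] == ["A", "C", "D"] and excluded == 1
    kept, excluded = missing_predictor_filter(records, "weight")
    assert [r.subject_id for r in kept] == ["A", "B", "C"] and excluded == 1


def test_cohort_frame_shape():
    frame = cohort_frame([_record("A"), _record("B")])
    assert list(frame["subject_id"]) == ["A", "B"]
    assert frame.shape == (2, 13)
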