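import datetime as dt
import textwrap
from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st

from mosvkit import (
    Anomaly,
    ColumnMap,
    EvidenceKind,
    IngestError,
    age_completed_months,
    builtin_schedule,
    clean_dates,
    impute_birth_day,
    read_children,
    select_cohort,
)

from conftest import make_child


def write_csv(tmp_path, body, header=None):
    header = header or (
        "child_id,dob_year,dob_month,dob_day,survey_date,card_seen,weight,"
        "stratum_id,cluster_id,BCG_date,DPT1_date,DPT1_recall"
    )
    p = tmp_path / "children.csv"
    p.write_text(header + "\n" + textwrap.dedent(body))
    return p


class TestReadChildren:
    def test_dated_blank_and_recall_cells(self, tmp_path):
        p = write_csv(
            tmp_path,
            """\
            k1,2017,3,15,2018-06-01,1,1.0,s,c,2017-03-16,,0
            k2,2017,3,15,2018-06-01,1,1.0,s,c,,,1
            k3,2017,3,15,2018-06-01,1,1.0,s,c,12/??/2017,,0
            """,
        )
        recs = {r.child_id: r for r in read_children(p)}
        assert recs["k1"].evidence_for("BCG").kind is EvidenceKind.DATE
        assert recs["k1"].evidence_for("BCG").date == dt.date(2017, 3, 16)
        assert recs["k1"].evidence_for("DPT1").kind is EvidenceKind.NONE
        assert recs["k2"].evidence_for("DPT1").kind is EvidenceKind.RECALL
        # illegible date: credited as a tick, no anomaly flags
        assert recs["k3"].evidence_for("BCG").kind is EvidenceKind.TICK
        assert not recs["k3"].evidence_for("BCG").anomaly_flags

    def test_recall_does_not_override_card_entry(self, tmp_path):
        p = write_csv(tmp_path, "k1,2017,3,15,2018-06-01,1,1.0,s,c,,2017-05-01,1\n")
        rec = read_children(p)[0]
        assert rec.evidence_for("DPT1").kind is EvidenceKind.DATE

    def test_missing_mandatory_column_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("child_id,survey_date\nk1,2018-06-01\n")
        with pytest.raises(IngestError, match="dob_year"):
            read_children(p)

    def test_duplicate_child_id_rejected(self, tmp_path):
        p = write_csv(
            tmp_path,
            """\
            k1,2017,3,15,2018-06-01,1,1.0,s,c,,,0
            k1,2017,3,15,2018-06-01,1,1.0,s,c,,,0
            """,
        )
        with pytest.raises(IngestError, match="duplicate"):
            read_children(p)

    def test_alias_mapping_renames_doses(self, tmp_path):
        header = (
            "child_id,dob_year,dob_month,dob_day,survey_date,card_seen,weight,"
            "stratum_id,cluster_id,PENTA1_date"
        )
        p = write_csv(tmp_path, "k1,2017,3,15,2018-06-01,1,1.0,s,c,2017-05-01\n", header)
        dialect = ColumnMap(aliases=builtin_schedule().alias_map())
        rec = read_children(p, dialect)[0]
        assert rec.evidence_for("DPT1").kind is EvidenceKind.DATE

    def test_missing_birth_day_leaves_dob_unresolved(self, tmp_path):
        p = write_csv(tmp_path, "k1,2017,3,,2018-06-01,1,1.0,s,c,2017-03-16,,0\n")
        rec = read_children(p)[0]
        assert rec.dob is None and rec.dob_month == 3


class TestImputeBirthDay:
    def test_birth_dose_in_birth_month_supplies_day(self, schedule):
        rec = make_child({"BCG": 0}, dob=dt.date(1990, 3, 15), survey_date=dt.date(1991, 6, 1))
        rec = replace(rec, dob=None, dob_day=None)
        out = impute_birth_day(rec, schedule)
        assert out.dob == dt.date(1990, 3, 15)
        assert out.dob_day_imputed

    def test_no_birth_dose_first_of_month(self, schedule):
        rec = make_child({"DPT1": 60}, dob=dt.date(1990, 3, 10), survey_date=dt.date(1991, 6, 1))
        rec = replace(rec, dob=None, dob_day=None)
        out = impute_birth_day(rec, schedule)
        assert out.dob == dt.date(1990, 3, 1)

    def test_birth_dose_outside_birth_month_ignored(self, schedule):
        # BCG dated in May cannot pin down a March birthday
        rec = make_child({"BCG": 53}, dob=dt.date(1990, 3, 10), survey_date=dt.date(1991, 6, 1))
        assert rec.evidence_for("BCG").date == dt.date(1990, 5, 2)
        rec = replace(rec, dob=None, dob_day=None)
        out = impute_birth_day(rec, schedule)
        assert out.dob == dt.date(1990, 3, 1)
        # no retained date may precede the imputed dob
        cleaned = clean_dates(out, schedule)
        assert all(
            ev.date >= out.dob
            for ev in cleaned.evidence.values()
            if ev.kind is EvidenceKind.DATE
        )

    def test_missing_month_passes_through_for_exclusion(self, schedule):
        rec = make_child({"BCG": 0})
        rec = replace(rec, dob=None, dob_day=None, dob_month=None)
        out = impute_birth_day(rec, schedule)
        assert out.dob is None


class TestCleanDates:
    def test_before_birth_and_after_survey_demoted(self, schedule):
        rec = make_child({"BCG": -5, "MCV1": 300, "DPT1": 50000})
        out = clean_dates(rec, schedule)
        assert out.evidence_for("BCG").kind is EvidenceKind.TICK
        assert Anomaly.BEFORE_BIRTH in out.evidence_for("BCG").anomaly_flags
        assert Anomaly.AFTER_SURVEY in out.evidence_for("DPT1").anomaly_flags
        assert out.evidence_for("MCV1").kind is EvidenceKind.DATE

    def test_out_of_order_keeps_maximal_consistent_prefix(self, schedule):
        # DPT2 precedes DPT1; DPT3 is checked against DPT1 (last retained)
        rec = make_child({"DPT1": 120, "DPT2": 108, "DPT3": 150})
        out = clean_dates(rec, schedule)
        assert out.evidence_for("DPT1").kind is EvidenceKind.DATE
        assert Anomaly.OUT_OF_ORDER in out.evidence_for("DPT2").anomaly_flags
        assert out.evidence_for("DPT3").kind is EvidenceKind.DATE

    def test_duplicate_series_date_demotes_later_dose(self, schedule):
        rec = make_child({"DPT1": 150, "DPT2": 181, "DPT3": 181})
        out = clean_dates(rec, schedule)
        assert out.evidence_for("DPT2").kind is EvidenceKind.DATE
        assert Anomaly.DUPLICATE_DATE_IN_SERIES in out.evidence_for("DPT3").anomaly_flags

    def test_consistent_record_unchanged(self, schedule):
        rec = make_child({"BCG": 1, "DPT1": 45, "DPT2": 75, "DPT3": 110})
        assert clean_dates(rec, schedule) == rec

    def test_absolute_check_runs_before_series_check(self, schedule):
        # DPT1's date is after the survey, so DPT2 is compared to nothing
        rec = make_child({"DPT1": 50000, "DPT2": 75})
        out = clean_dates(rec, schedule)
        assert Anomaly.AFTER_SURVEY in out.evidence_for("DPT1").anomaly_flags
        assert out.evidence_for("DPT2").kind is EvidenceKind.DATE


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    ages=st.lists(st.integers(-30, 600), min_size=0, max_size=6),
)
def test_cleaning_idempotent_and_credit_preserving(ages):
    """clean∘clean == clean, and no child loses credit for any dose."""
    schedule = builtin_schedule("epi_nigeria")
    names = ["BCG", "OPV1", "DPT1", "DPT2", "DPT3", "MCV1"]
    rec = make_child(dict(zip(names, ages)))
    once = clean_dates(rec, schedule)
    assert clean_dates(once, schedule) == once
    before = sum(ev.kind is not EvidenceKind.NONE for ev in rec.evidence.values())
    after = sum(ev.kind is not EvidenceKind.NONE for ev in once.evidence.values())
    assert before == after


class TestSelectCohort:
    def test_filters_and_partition(self, schedule):
        dob_ok = dt.date(2017, 2, 1)
        recs = [
            make_child({"BCG": 1}, child_id="in1"),
            make_child({"BCG": 1}, child_id="nocard", card_seen=False),
            make_child({"BCG": "tick"}, child_id="nodates"),
            make_child({"BCG": 1}, dob=dt.date(2016, 3, 1), child_id="tooold"),
            make_child({"BCG": 1}, dob=dt.date(2017, 9, 1), child_id="tooyoung"),
        ]
        nodob = replace(recs[0], child_id="nodob", dob=None)
        recs.append(nodob)
        sel = select_cohort(recs)
        assert [r.child_id for r in sel.included] == ["in1"]
        assert sel.excluded_no_card == 1
        assert sel.excluded_no_dates == 1
        assert sel.excluded_age == 2
        assert sel.excluded_no_dob == 1
        assert sel.n_input == len(recs)
        assert dob_ok == recs[0].dob  # sanity: the included child is 16 months

    def test_age_window_boundaries(self, schedule):
        survey = dt.date(2018, 6, 1)
        just_12m = make_child({"BCG": 1}, dob=dt.date(2017, 6, 1), survey_date=survey)
        just_under_12m = make_child({"BCG": 1}, dob=dt.date(2017, 6, 2), survey_date=survey)
        just_under_24m = make_child({"BCG": 1}, dob=dt.date(2016, 6, 2), survey_date=survey)
        exactly_24m = make_child({"BCG": 1}, dob=dt.date(2016, 6, 1), survey_date=survey)
        sel = select_cohort([just_12m, just_under_12m, just_under_24m, exactly_24m])
        assert len(sel.included) == 2
        assert sel.excluded_age == 2


@pytest.mark.parametrize(
    "dob, on, months",
    [
        (dt.date(2017, 6, 1), dt.date(2018, 6, 1), 12),
        (dt.date(2017, 6, 2), dt.date(2018, 6, 1), 11),
        (dt.date(2016, 6, 1), dt.date(2018, 5, 31), 23),
        (dt.date(2017, 1, 31), dt.date(2017, 4, 30), 3),  # anniversary clamped to month end
        (dt.date(2017, 1, 31), dt.date(2017, 4, 29), 2),
    ],
)
def test_age_completed_months(dob, on, months):
    assert age_completed_months(dob, on) == months
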