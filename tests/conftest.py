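import datetime as dt

import pytest

from mosvkit import (
    ChildRecord,
    DoseEvidence,
    EvidenceKind,
    builtin_schedule,
)

SURVEY = dt.date(2018, 6, 1)


@pytest.fixture(scope="session")
def schedule():
    """Eight classic EPI doses plus OPV birth dose (Nigeria-style profile)."""
    return builtin_schedule("epi_nigeria")


@pytest.fixture(scope="session")
def colombia_schedule():
    return builtin_schedule("epi_colombia")


def make_child(
    doses: dict[str, int | str | None],
    dob: dt.date = dt.date(2017, 2, 1),
    survey_date: dt.date = SURVEY,
    child_id: str = "c1",
    weight: float = 1.0,
    card_seen: bool = True,
    stratum_id: str = "s1",
) -> ChildRecord:
    """Build a child whose doses are given at ages in days.

    ``doses`` maps dose name to an age in days (dated evidence), the string
    ``"tick"`` / ``"recall"``, or ``None`` (no evidence).
    """
    evidence = {}
    for name, spec in doses.items():
        if spec is None:
            evidence[name] = DoseEvidence(EvidenceKind.NONE)
        elif spec == "tick":
            evidence[name] = DoseEvidence(EvidenceKind.TICK)
        elif spec == "recall":
            evidence[name] = DoseEvidence(EvidenceKind.RECALL)
        else:
            evidence[name] = DoseEvidence(
                EvidenceKind.DATE, dob + dt.timedelta(days=int(spec))
            )
    return ChildRecord(
        child_id=child_id,
        survey_date=survey_date,
        card_seen=card_seen,
        weight=weight,
        stratum_id=stratum_id,
        cluster_id="cl1",
        dob=dob,
        dob_year=dob.year,
        dob_month=dob.month,
        dob_day=dob.day,
        evidence=evidence,
    )
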