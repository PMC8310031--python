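"""Child-level survey ingestion: evidence model, date cleaning, cohort filters.

The analysis consumes one row per surveyed child with a date of birth
(possibly day-missing), the interview date, a card-seen flag, survey design
columns (weight, stratum, cluster) and per-dose evidence.  Evidence comes in
four kinds:

* ``DATE`` — a legible dated card entry; the only kind usable for visit
  reconstruction;
* ``TICK`` — card entry without a usable date; the child is credited with the
  dose but the entry cannot anchor a visit;
* ``RECALL`` — caregiver report only;
* ``NONE`` — no evidence.

Cleaning demotes nonsensical dates (before birth, after the survey,
out-of-order or duplicated within a series) to tick marks, recording why, so
the child keeps credit for the dose while the bad date stays out of the
analysis.  The cohort is then children aged 12-23 completed months whose card
was seen, whose birth month and year are known, and who have at least one
retained vaccination date.
"""

from __future__ import annotations

import calendar
import datetime as dt
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .schedule import Schedule

__all__ = [
    "EvidenceKind",
    "Anomaly",
    "DoseEvidence",
    "ChildRecord",
    "CohortSelection",
    "ColumnMap",
    "IngestError",
    "read_children",
    "impute_birth_day",
    "clean_dates",
    "select_cohort",
    "age_completed_months",
]


class IngestError(ValueError):
    """Raised for malformed input tables (missing columns, duplicate ids)."""


class EvidenceKind(str, enum.Enum):
    DATE = "DATE"
    TICK = "TICK"
    RECALL = "RECALL"
    NONE = "NONE"


class Anomaly(str, enum.Enum):
    """Why a recorded date was demoted to a tick mark during cleaning."""

    BEFORE_BIRTH = "BEFORE_BIRTH"
    AFTER_SURVEY = "AFTER_SURVEY"
    OUT_OF_ORDER = "OUT_OF_ORDER"
    DUPLICATE_DATE_IN_SERIES = "DUPLICATE_DATE_IN_SERIES"


@dataclass(frozen=True)
class DoseEvidence:
    kind: EvidenceKind = EvidenceKind.NONE
    date: Optional[dt.date] = None
    anomaly_flags: frozenset[Anomaly] = frozenset()

    def __post_init__(self) -> None:
        if self.kind is EvidenceKind.DATE:
            if self.date is None:
                raise ValueError("DATE evidence requires a date")
            if self.anomaly_flags:
                raise ValueError("DATE evidence cannot carry anomaly flags")
        elif self.date is not None:
            raise ValueError(f"{self.kind.value} evidence cannot carry a date")

    @property
    def received(self) -> bool:
        """Any positive evidence of receipt (date, tick or recall)."""
        return self.kind is not EvidenceKind.NONE


_NO_EVIDENCE = DoseEvidence()


@dataclass(frozen=True)
class ChildRecord:
    """One surveyed child.

    ``dob`` is ``None`` until the birth date is resolved; records whose birth
    month or year is missing keep ``dob=None`` and are routed to the
    ``excluded_no_dob`` tally by :func:`select_cohort` rather than raising.
    """

    child_id: str
    survey_date: dt.date
    card_seen: bool
    weight: float
    stratum_id: str = ""
    cluster_id: str = ""
    dob: Optional[dt.date] = None
    dob_year: Optional[int] = None
    dob_month: Optional[int] = None
    dob_day: Optional[int] = None
    dob_day_imputed: bool = False
    evidence: Mapping[str, DoseEvidence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"{self.child_id}: weight must be >= 0")
        if self.dob is not None and self.dob >= self.survey_date:
            raise ValueError(f"{self.child_id}: dob must precede survey_date")

    def evidence_for(self, dose_name: str) -> DoseEvidence:
        return self.evidence.get(dose_name, _NO_EVIDENCE)

    def dated_doses(self) -> dict[str, dt.date]:
        return {
            name: ev.date
            for name, ev in self.evidence.items()
            if ev.kind is EvidenceKind.DATE
        }

    def age_days_at(self, date: dt.date) -> int:
        if self.dob is None:
            raise ValueError(f"{self.child_id}: dob not resolved")
        return (date - self.dob).days


@dataclass
class CohortSelection:
    """Outcome of applying the analysis filters to a cleaned record list."""

    included: list[ChildRecord]
    excluded_no_card: int = 0
    excluded_no_dob: int = 0
    excluded_age: int = 0
    excluded_no_dates: int = 0

    @property
    def n_input(self) -> int:
        return (
            len(self.included)
            + self.excluded_no_card
            + self.excluded_no_dob
            + self.excluded_age
            + self.excluded_no_dates
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("input", self.n_input),
                ("included", len(self.included)),
                ("excluded_no_card", self.excluded_no_card),
                ("excluded_no_dob", self.excluded_no_dob),
                ("excluded_age", self.excluded_age),
                ("excluded_no_dates", self.excluded_no_dates),
            ],
            columns=["category", "n"],
        )


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from the logical input contract onto actual CSV column names.

    Per-dose evidence columns are discovered by suffix: ``<dose>_date`` holds
    ISO dates (or free text for illegible entries, or a bare tick token) and
    ``<dose>_recall`` holds a caregiver-recall flag.  ``aliases`` renames
    survey-specific dose labels (e.g. ``PENTA1``) onto canonical schedule
    names before anything else happens.
    """

    child_id: str = "child_id"
    dob_year: str = "dob_year"
    dob_month: str = "dob_month"
    dob_day: str = "dob_day"
    survey_date: str = "survey_date"
    card_seen: str = "card_seen"
    weight: str = "weight"
    stratum_id: str = "stratum_id"
    cluster_id: str = "cluster_id"
    date_suffix: str = "_date"
    recall_suffix: str = "_recall"
    aliases: Mapping[str, str] = field(default_factory=dict)

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (
            self.child_id,
            self.dob_year,
            self.dob_month,
            self.survey_date,
            self.card_seen,
            self.weight,
        )


_TRUTHY = {"1", "true", "yes", "y", "t"}
_TICK_TOKENS = {"tick", "x", "+"}


def _parse_date(text: str) -> Optional[dt.date]:
    try:
        return dt.date.fromisoformat(text)
    except ValueError:
        return None


def _parse_int(value) -> Optional[int]:
    if value is None:
        return None
    text = str(value).strip()
    if not text:
        return None
    try:
        return int(float(text))
    except ValueError:
        return None


def _parse_bool(value) -> bool:
    return str(value).strip().lower() in _TRUTHY


def read_children(path: str | Path, dialect: ColumnMap | None = None) -> list[ChildRecord]:
    """Read raw child records from a CSV file.

    Vaccination-date cells that do not parse as ISO dates become ``TICK``
    evidence with no anomaly flags (the "illegible date" rule); blank cells
    become ``NONE``; truthy recall cells become ``RECALL`` when no dated or
    ticked card entry exists for that dose.  The day of birth may be blank.
    """
    dialect = dialect or ColumnMap()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in dialect.mandatory if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing mandatory column(s) {missing}")

    date_cols = [c for c in df.columns if c.endswith(dialect.date_suffix)]
    recall_cols = [c for c in df.columns if c.endswith(dialect.recall_suffix)]
    # survey_date matches the *_date suffix but is not a dose column
    date_cols = [c for c in date_cols if c != dialect.survey_date]

    def dose_of(col: str, suffix: str) -> str:
        name = col[: -len(suffix)]
        return dialect.aliases.get(name, name)

    records: list[ChildRecord] = []
    seen_ids: set[str] = set()
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        child_id = str(row[dialect.child_id]).strip()
        if child_id in seen_ids:
            raise IngestError(f"duplicate child_id {child_id!r}")
        seen_ids.add(child_id)

        survey_date = _parse_date(str(row[dialect.survey_date]).strip())
        if survey_date is None:
            raise IngestError(f"child {child_id}: unparseable survey_date")

        evidence: dict[str, DoseEvidence] = {}
        for col in date_cols:
            cell = str(row[col]).strip()
            if not cell:
                continue
            dose = dose_of(col, dialect.date_suffix)
            date = _parse_date(cell)
            if date is not None:
                evidence[dose] = DoseEvidence(EvidenceKind.DATE, date)
            else:
                # Any non-blank, non-date content is an illegible entry or an
                # explicit tick token: credit without a usable date.
                evidence[dose] = DoseEvidence(EvidenceKind.TICK)
        for col in recall_cols:
            if not _parse_bool(row[col]):
                continue
            dose = dose_of(col, dialect.recall_suffix)
            if dose not in evidence:
                evidence[dose] = DoseEvidence(EvidenceKind.RECALL)

        dob_year = _parse_int(row.get(dialect.dob_year))
        dob_month = _parse_int(row.get(dialect.dob_month))
        dob_day = _parse_int(row.get(dialect.dob_day)) if dialect.dob_day in df.columns else None
        dob = None
        if dob_year is not None and dob_month is not None and dob_day is not None:
            try:
                dob = dt.date(dob_year, dob_month, dob_day)
            except ValueError:
                dob = None
        weight_text = str(row[dialect.weight]).strip()
        records.append(
            ChildRecord(
                child_id=child_id,
                survey_date=survey_date,
                card_seen=_parse_bool(row[dialect.card_seen]),
                weight=float(weight_text) if weight_text else 1.0,
                stratum_id=str(row.get(dialect.stratum_id, "") or ""),
                cluster_id=str(row.get(dialect.cluster_id, "") or ""),
                dob=dob,
                dob_year=dob_year,
                dob_month=dob_month,
                dob_day=dob_day,
                evidence=evidence,
            )
        )
    return records


def impute_birth_day(record: ChildRecord, schedule: Schedule) -> ChildRecord:
    """Resolve a missing day of birth.

    When only month and year are known, the day is taken from a dated birth
    dose (minimum age 0) falling inside the reported birth month — the
    earliest such date if several — and otherwise set to the first day of the
    month.  Restricting to the birth month guarantees no vaccination date can
    precede the imputed birth date.  Records missing birth month or year are
    returned unchanged (``dob`` stays ``None``) for downstream exclusion.
    """
    if record.dob is not None:
        return record
    if record.dob_year is None or record.dob_month is None:
        return record
    year, month = record.dob_year, record.dob_month
    candidates = []
    for dose in schedule.birth_doses():
        ev = record.evidence_for(dose.dose_name)
        if ev.kind is EvidenceKind.DATE and (ev.date.year, ev.date.month) == (year, month):
            candidates.append(ev.date)
    if candidates:
        dob = min(candidates)
    else:
        dob = dt.date(year, month, 1)
    if dob >= record.survey_date:
        return record  # unresolvable: interviewed before/on the imputed dob
    return replace(record, dob=dob, dob_day=dob.day, dob_day_imputed=True)


def _demote(ev: DoseEvidence, flag: Anomaly) -> DoseEvidence:
    return DoseEvidence(EvidenceKind.TICK, None, ev.anomaly_flags | {flag})


def clean_dates(record: ChildRecord, schedule: Schedule) -> ChildRecord:
    """Demote nonsensical vaccination dates to tick marks.

    Two fixed passes. First, absolute checks: any date before birth or after
    the survey date is removed.  Second, within each series in dose-number
    order, a dose dated on or before the last retained dated dose of the
    series is removed (flagged out-of-order if strictly earlier, duplicate if
    equal), and later doses keep being checked against the last *retained*
    date.  The child keeps credit for every demoted dose; tick and recall
    evidence is untouched.  The operation is total and idempotent.
    """
    if record.dob is None:
        return record
    evidence = dict(record.evidence)

    for name, ev in evidence.items():
        if ev.kind is not EvidenceKind.DATE:
            continue
        if ev.date < record.dob:
            evidence[name] = _demote(ev, Anomaly.BEFORE_BIRTH)
        elif ev.date > record.survey_date:
            evidence[name] = _demote(ev, Anomaly.AFTER_SURVEY)

    series_ids = {d.series_id for d in schedule if d.series_id is not None}
    for series in series_ids:
        last_retained: Optional[dt.date] = None
        for dose in schedule.series_doses(series):
            ev = evidence.get(dose.dose_name)
            if ev is None or ev.kind is not EvidenceKind.DATE:
                continue
            if last_retained is not None and ev.date <= last_retained:
                flag = (
                    Anomaly.DUPLICATE_DATE_IN_SERIES
                    if ev.date == last_retained
                    else Anomaly.OUT_OF_ORDER
                )
                evidence[dose.dose_name] = _demote(ev, flag)
            else:
                last_retained = ev.date
    return replace(record, evidence=evidence)


def age_completed_months(dob: dt.date, on: dt.date) -> int:
    """Age in completed calendar months (floor), adjusting for the day."""
    months = (on.year - dob.year) * 12 + (on.month - dob.month)
    # month-birthday falls on the month's last day when dob.day does not exist
    anniversary_day = min(dob.day, calendar.monthrange(on.year, on.month)[1])
    if on.day < anniversary_day:
        months -= 1
    return months


def select_cohort(
    records: Iterable[ChildRecord],
    age_window_months: tuple[int, int] = (12, 24),
) -> CohortSelection:
    """Apply the analysis filters and tally exclusions.

    A child enters the cohort when the card was seen, the birth date is
    resolved, age at survey lies in ``[lo, hi)`` completed months, and at
    least one retained dated dose exists.  Each excluded child is counted
    once, under the first failing filter (card, birth date, age, dates).
    """
    lo, hi = age_window_months
    sel = CohortSelection(included=[])
    for rec in records:
        if not rec.card_seen:
            sel.excluded_no_card += 1
            continue
        if rec.dob is None:
            sel.excluded_no_dob += 1
            continue
        age_m = age_completed_months(rec.dob, rec.survey_date)
        if not (lo <= age_m < hi):
            sel.excluded_age += 1
            continue
        if not rec.dated_doses():
            sel.excluded_no_dates += 1
            continue
        sel.included.append(rec)
    return sel
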