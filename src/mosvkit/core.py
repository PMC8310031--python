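"""Visit reconstruction, dose accounting and MOSV detection.

A *visit* is a distinct vaccination date on a child's card; every dated dose
anchors one, whether or not the dose is summarized.  At each visit the child
was eligible for some set of doses given their age and receipt history; a
missed opportunity for simultaneous vaccination (MOSV) is a summarized dose
that was due at that visit but not administered there.

Two accountings of "received" are supported:

* ``CRUDE`` — any dated dose counts as itself, regardless of the age at
  receipt or the interval since the previous dose;
* ``VALID`` — doses given too early or after too short an interval are
  invalid, and a later administration may fill an earlier slot of the series
  (an administered second dose can count as the first).

Visit eligibility respects minimum ages and intervals in both modes; the
crude/valid distinction governs only which received doses count.  Tick-mark
and recall evidence means "received, date unknown": such doses never generate
events, satisfy prerequisites as if received before every dated visit, and do
not anchor visits.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from typing import Optional

from .ingest import ChildRecord, EvidenceKind
from .schedule import Schedule, eligible_for

__all__ = [
    "Mode",
    "INVALID",
    "Visit",
    "VisitAnnotation",
    "DoseAccounting",
    "MOSVEvent",
    "reconstruct_visits",
    "reallocate_valid_doses",
    "crude_accounting",
    "dose_accounting",
    "annotate_visits",
    "detect_mosvs",
    "counterfactual_receipt",
]


class Mode(str, enum.Enum):
    CRUDE = "CRUDE"
    VALID = "VALID"


#: Sentinel reallocation target for administered doses that count as nothing.
INVALID = "INVALID"


@dataclass(frozen=True)
class Visit:
    date: dt.date
    age_days: int
    doses_administered: frozenset[str]

    def __post_init__(self) -> None:
        if not self.doses_administered:
            raise ValueError("a visit must administer at least one dose")
        if self.age_days < 0:
            raise ValueError("visit before birth; run date cleaning first")


@dataclass(frozen=True)
class VisitAnnotation:
    """One visit with the eligibility verdicts used by MOSV detection.

    ``eligible`` holds the summarized doses due at the visit given the
    mode-specific receipt history; ``counted_administered`` the summarized
    doses administered *and counted* there; ``missed`` their difference.
    """

    visit: Visit
    eligible: frozenset[str]
    counted_administered: frozenset[str]
    missed: frozenset[str]


@dataclass(frozen=True)
class DoseAccounting:
    """Which administered doses count as received, and as what."""

    mode: Mode
    counted_receipt: dict[str, dt.date]
    reallocation: dict[str, str]


@dataclass(frozen=True)
class MOSVEvent:
    """One (child, dose) missed opportunity, possibly spanning several visits."""

    child_id: str
    dose_name: str
    first_missed_date: dt.date
    n_missed_visits: int
    corrected: bool
    correction_date: Optional[dt.date] = None
    delay_days: Optional[int] = None

    def __post_init__(self) -> None:
        if self.corrected:
            if self.correction_date is None or self.delay_days is None:
                raise ValueError("corrected event needs correction_date and delay")
            if self.delay_days != (self.correction_date - self.first_missed_date).days:
                raise ValueError("delay_days inconsistent with dates")
            if self.delay_days < 1:
                raise ValueError("correction must postdate the first miss")
        elif self.correction_date is not None or self.delay_days is not None:
            raise ValueError("uncorrected event cannot carry correction fields")


def reconstruct_visits(record: ChildRecord) -> list[Visit]:
    """Group the child's dated doses into visits, one per distinct date.

    Every dated dose participates — summarized or not, on or off the analysis
    schedule — because any documented administration marks a contact at which
    other doses could have been given.
    """
    by_date: dict[dt.date, set[str]] = {}
    for name, date in record.dated_doses().items():
        by_date.setdefault(date, set()).add(name)
    return [
        Visit(date=d, age_days=record.age_days_at(d), doses_administered=frozenset(doses))
        for d, doses in sorted(by_date.items())
    ]


def _tick_doses(record: ChildRecord) -> set[str]:
    return {
        name
        for name, ev in record.evidence.items()
        if ev.kind in (EvidenceKind.TICK, EvidenceKind.RECALL)
    }


def reallocate_valid_doses(record: ChildRecord, schedule: Schedule) -> DoseAccounting:
    """Valid-dose accounting with slot reallocation within each series.

    Administered dated doses of a series are scanned in date order and fill
    dose slots 1, 2, 3 in turn: a dose is valid if the child's age meets the
    next unfilled slot's minimum age and the interval since the previously
    counted dose meets that slot's minimum interval.  An administered second
    dose may therefore count as the first when the documented first dose was
    given too early.  Standalone doses are validated on age alone.  Tick-mark
    evidence never fills a slot (its timing cannot be verified).
    """
    dated = record.dated_doses()
    counted: dict[str, dt.date] = {}
    realloc: dict[str, str] = {}

    series_ids: list[str] = []
    for d in schedule:
        if d.series_id is not None and d.series_id not in series_ids:
            series_ids.append(d.series_id)

    for series in series_ids:
        slots = schedule.series_doses(series)
        administered = sorted(
            ((dated[d.dose_name], d.dose_name) for d in slots if d.dose_name in dated)
        )
        s = 0
        for date, label in administered:
            if s >= len(slots):
                realloc[label] = INVALID
                continue
            slot = slots[s]
            age = record.age_days_at(date)
            ok = age >= slot.min_age_days
            if ok and s > 0:
                prev_date = counted[slots[s - 1].dose_name]
                ok = (date - prev_date).days >= slot.min_interval_days
            if ok:
                counted[slot.dose_name] = date
                realloc[label] = slot.dose_name
                s += 1
            else:
                realloc[label] = INVALID

    for d in schedule:
        if d.series_id is not None or d.dose_name not in dated:
            continue
        date = dated[d.dose_name]
        if record.age_days_at(date) >= d.min_age_days:
            counted[d.dose_name] = date
            realloc[d.dose_name] = d.dose_name
        else:
            realloc[d.dose_name] = INVALID

    # Dated doses outside the schedule cannot be validated; count them as
    # themselves so they still block re-offering and anchor visits.
    for name, date in dated.items():
        if name not in realloc:
            counted[name] = date
            realloc[name] = name

    return DoseAccounting(Mode.VALID, counted, realloc)


def crude_accounting(record: ChildRecord) -> DoseAccounting:
    """Crude accounting: every dated dose counts as itself."""
    dated = record.dated_doses()
    return DoseAccounting(Mode.CRUDE, dict(dated), {n: n for n in dated})


def dose_accounting(record: ChildRecord, schedule: Schedule, mode: Mode) -> DoseAccounting:
    if Mode(mode) is Mode.CRUDE:
        return crude_accounting(record)
    return reallocate_valid_doses(record, schedule)


def annotate_visits(
    record: ChildRecord, schedule: Schedule, mode: Mode
) -> list[VisitAnnotation]:
    """Walk the child's visits and mark eligibility and misses per visit."""
    mode = Mode(mode)
    visits = reconstruct_visits(record)
    acct = dose_accounting(record, schedule, mode)
    ticks = _tick_doses(record)

    annotations: list[VisitAnnotation] = []
    for visit in visits:
        history: dict[str, Optional[dt.date]] = {
            name: date for name, date in acct.counted_receipt.items() if date < visit.date
        }
        for name in ticks:
            history.setdefault(name, None)

        if mode is Mode.CRUDE:
            counted_here = visit.doses_administered
        else:
            counted_here = frozenset(
                slot
                for label, slot in acct.reallocation.items()
                if slot != INVALID and record.dated_doses()[label] == visit.date
            )

        eligible = frozenset(
            d.dose_name
            for d in schedule.summarized_doses
            if eligible_for(d, visit.age_days, history, visit.date, schedule)
        )
        missed = frozenset(eligible - counted_here)
        annotations.append(
            VisitAnnotation(
                visit=visit,
                eligible=eligible,
                counted_administered=frozenset(counted_here),
                missed=missed,
            )
        )
    return annotations


def detect_mosvs(
    record: ChildRecord, schedule: Schedule, mode: Mode = Mode.CRUDE
) -> list[MOSVEvent]:
    """Detect missed opportunities for simultaneous vaccination for one child.

    Returns one event per (child, dose) with the date of the first missed
    visit, the number of visits at which the dose was missed, and whether a
    counted administration of the dose followed later (a *corrected* MOSV)
    together with the delay in days.  Events are ordered by first missed date
    then dose name.
    """
    mode = Mode(mode)
    acct = dose_accounting(record, schedule, mode)
    first_missed: dict[str, dt.date] = {}
    n_missed: dict[str, int] = {}
    for ann in annotate_visits(record, schedule, mode):
        for dose in ann.missed:
            first_missed.setdefault(dose, ann.visit.date)
            n_missed[dose] = n_missed.get(dose, 0) + 1

    events = []
    for dose, first_date in first_missed.items():
        received = acct.counted_receipt.get(dose)
        corrected = received is not None and received > first_date
        events.append(
            MOSVEvent(
                child_id=record.child_id,
                dose_name=dose,
                first_missed_date=first_date,
                n_missed_visits=n_missed[dose],
                corrected=corrected,
                correction_date=received if corrected else None,
                delay_days=(received - first_date).days if corrected else None,
            )
        )
    events.sort(key=lambda e: (e.first_missed_date, e.dose_name))
    return events


def counterfactual_receipt(
    record: ChildRecord, schedule: Schedule
) -> dict[str, Optional[dt.date]]:
    """Receipt map had every due dose been given at every attended visit.

    Walks the child's visits in order, crediting every summarized dose that
    is eligible given the counterfactual history; the visit date becomes the
    counterfactual receipt date.  Credits granted at a visit do not unlock
    further doses at that same visit (intervals are measured from strictly
    earlier receipts).  Tick/recall doses seed the map with unknown dates.
    """
    receipt: dict[str, Optional[dt.date]] = {name: None for name in _tick_doses(record)}
    for visit in reconstruct_visits(record):
        history = {
            name: date
            for name, date in receipt.items()
            if date is None or date < visit.date
        }
        due = [
            d
            for d in schedule.summarized_doses
            if eligible_for(d, visit.age_days, history, visit.date, schedule)
        ]
        for d in due:
            receipt[d.dose_name] = visit.date
    return receipt
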