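"""Brute-force day-stepping MOSV oracle, independent of mosvkit.core.

Re-derives eligibility from scratch for every visit date by stepping through
every day of the child's life and asking, per dose, whether the dose was due
that day given the counted receipt history.  Deliberately slow and simple —
no shared helpers with the implementation under test beyond the record and
schedule containers.
"""

from __future__ import annotations

import datetime as dt

from mosvkit.ingest import ChildRecord, EvidenceKind
from mosvkit.schedule import Schedule


def _dated(record: ChildRecord) -> dict[str, dt.date]:
    return {
        n: ev.date for n, ev in record.evidence.items() if ev.kind is EvidenceKind.DATE
    }


def _ticked(record: ChildRecord) -> set[str]:
    return {
        n
        for n, ev in record.evidence.items()
        if ev.kind in (EvidenceKind.TICK, EvidenceKind.RECALL)
    }


def oracle_valid_counted(record: ChildRecord, schedule: Schedule) -> dict[str, dt.date]:
    """Valid-dose accounting recomputed from first principles.

    For each series, walk the child's dated administrations of that series
    chronologically; each either fills the next open slot (age and interval
    permitting) or is thrown away.  Standalone doses need only meet their
    minimum age.
    """
    dated = _dated(record)
    counted: dict[str, dt.date] = {}
    series_ids = []
    for d in schedule:
        if d.series_id and d.series_id not in series_ids:
            series_ids.append(d.series_id)
    for sid in series_ids:
        slots = schedule.series_doses(sid)
        shots = sorted(dated[d.dose_name] for d in slots if d.dose_name in dated)
        filled: list[dt.date] = []
        for shot in shots:
            if len(filled) >= len(slots):
                break
            slot = slots[len(filled)]
            age = (shot - record.dob).days
            if age < slot.min_age_days:
                continue
            if filled and (shot - filled[-1]).days < slot.min_interval_days:
                continue
            filled.append(shot)
        for slot, date in zip(slots, filled):
            counted[slot.dose_name] = date
    for d in schedule:
        if d.series_id is None and d.dose_name in dated:
            if (dated[d.dose_name] - record.dob).days >= d.min_age_days:
                counted[d.dose_name] = dated[d.dose_name]
    for name, date in dated.items():
        if name not in schedule.dose_names:
            counted[name] = date
    return counted


def _due_days(
    record: ChildRecord,
    schedule: Schedule,
    counted: dict[str, dt.date],
    ticked: set[str],
) -> dict[str, set[int]]:
    """For each summarized dose, the set of ages (in days) at which it was due.

    Day-stepping: for every day from birth to the survey, check all clauses
    of eligibility directly against the counted receipt dates.
    """
    horizon = (record.survey_date - record.dob).days
    due: dict[str, set[int]] = {}
    for dose in schedule.summarized_doses:
        name = dose.dose_name
        days: set[int] = set()
        if name in ticked:
            due[name] = days  # credited as received: never due
            continue
        prev_name = None
        if dose.series_id is not None and dose.dose_number > 1:
            for other in schedule:
                if (
                    other.series_id == dose.series_id
                    and other.dose_number == dose.dose_number - 1
                ):
                    prev_name = other.dose_name
        for day in range(horizon + 1):
            date = record.dob + dt.timedelta(days=day)
            if name in counted and counted[name] < date:
                continue  # already received
            if day < dose.min_age_days:
                continue
            if dose.max_age_days is not None and day > dose.max_age_days:
                continue
            if prev_name is not None:
                if prev_name in ticked:
                    pass  # unknown date: assumed long enough ago
                elif prev_name in counted and counted[prev_name] < date:
                    if (date - counted[prev_name]).days < dose.min_interval_days:
                        continue
                else:
                    continue
            days.add(day)
        due[name] = days
    return due


def oracle_detect(record: ChildRecord, schedule: Schedule, mode: str):
    """Events as (dose, first_missed_date, n_missed, corrected, delay) tuples."""
    dated = _dated(record)
    ticked = _ticked(record)
    if str(mode).upper().endswith("CRUDE"):
        counted = dict(dated)
    else:
        counted = oracle_valid_counted(record, schedule)
    due = _due_days(record, schedule, counted, ticked)
    visit_dates = sorted(set(dated.values()))

    results = {}
    for name, days in due.items():
        missed_dates = []
        for vd in visit_dates:
            day = (vd - record.dob).days
            if day not in days:
                continue
            if counted.get(name) == vd:
                continue  # administered and counted at this very visit
            missed_dates.append(vd)
        if not missed_dates:
            continue
        first = missed_dates[0]
        got = counted.get(name)
        corrected = got is not None and got > first
        results[name] = (
            name,
            first,
            len(missed_dates),
            corrected,
            (got - first).days if corrected else None,
        )
    return sorted(results.values(), key=lambda t: (t[1], t[0]))
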