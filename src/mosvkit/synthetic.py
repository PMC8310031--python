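"""DHS-like synthetic cohort generator with known MOSV ground truth.

Emulates the structure of a child-recode vaccination table: a 12-23-month
cohort interviewed on a common survey date, partial card availability,
dated doses for the classic EPI antigens, per-visit miss events with later
corrections, and (optionally) corrupted dates.  The visit process is
schedule-anchored — children attend around the recommended ages, with
normal jitter and per-visit dropout — rather than a Poisson contact
process, which keeps eligible-visit denominators predictable.

The generator records its own truth table while simulating: the visits a
card would show and, at each *observable* visit (one where at least one dose
was administered), which eligible summarized doses were not given.  Visits
where every due dose was missed leave no dated entry and are therefore
unobservable to any date-based analysis; they are dropped from both the
record and the truth.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import MOSVEvent, Visit
from .ingest import ChildRecord, DoseEvidence, EvidenceKind, age_completed_months
from .schedule import Schedule, builtin_schedule, eligible_for

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "generate",
    "write_children_csv",
    "write_truth_csv",
]

JITTER_TRUNCATION_DAYS = 21


@dataclass(frozen=True)
class SyntheticParams:
    """Configuration of the simulated survey world.

    Defaults describe a mid-card-availability setting: 60% of caregivers can
    show a card (observed national values span roughly 20-85%), visits target
    the recommended ages with a week of jitter, each scheduled contact is
    skipped with probability 0.1, each due dose is missed at an eligible
    visit with probability 0.15, and a missed dose is given at any later
    eligible visit with probability 0.5.  2% of recorded dates are corrupted
    (equal shares before-birth, after-survey, swapped-within-series).
    """

    n_children: int = 1000
    seed: int = 0
    survey_date: dt.date = dt.date(2018, 6, 1)
    card_prob: float = 0.6
    visit_ages_days: tuple[int, ...] = (0, 42, 70, 98, 270)
    jitter_sd_days: float = 7.0
    attendance_dropout: float = 0.1
    miss_prob: Mapping[str, float] | float = 0.15
    correction_prob: float = 0.5
    date_error_rate: float = 0.02
    weight_model: str = "EQUAL"  # or "LOGNORMAL"
    weight_lognormal_sd: float = 0.5
    strata: tuple[tuple[str, float], ...] = (("north", 0.5), ("south", 0.5))
    clusters_per_stratum: int = 10

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        if not self.visit_ages_days:
            raise ValueError("at least one target visit age is required")
        if list(self.visit_ages_days) != sorted(self.visit_ages_days):
            raise ValueError("visit_ages_days must be increasing")
        probs = [self.card_prob, self.attendance_dropout, self.correction_prob, self.date_error_rate]
        if isinstance(self.miss_prob, Mapping):
            probs.extend(self.miss_prob.values())
        else:
            probs.append(self.miss_prob)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.weight_model not in ("EQUAL", "LOGNORMAL"):
            raise ValueError("weight_model must be EQUAL or LOGNORMAL")
        total = sum(p for _, p in self.strata)
        if not np.isclose(total, 1.0):
            raise ValueError("stratum proportions must sum to 1")

    def miss_prob_for(self, dose_name: str, summarized: bool) -> float:
        if isinstance(self.miss_prob, Mapping):
            return float(self.miss_prob.get(dose_name, 0.0))
        return float(self.miss_prob) if summarized else 0.0


@dataclass
class SyntheticTruth:
    """Ground truth per child: observable visits, MOSV events, anomalies."""

    visits: dict[str, list[Visit]] = field(default_factory=dict)
    events: dict[str, list[MOSVEvent]] = field(default_factory=dict)
    anomalies: list[tuple[str, str, str]] = field(default_factory=list)  # child, dose, kind

    def all_events(self) -> list[MOSVEvent]:
        return [e for evs in self.events.values() for e in evs]


def _truncated_jitter(rng: np.random.Generator, sd: float) -> float:
    while True:
        j = rng.normal(0.0, sd)
        if abs(j) <= JITTER_TRUNCATION_DAYS:
            return j


def _draw_age_days(rng: np.random.Generator, survey_date: dt.date) -> int:
    # Rejection-sample until the completed-month age lands in [12, 24).
    while True:
        age = int(rng.integers(360, 736))
        dob = survey_date - dt.timedelta(days=age)
        if 12 <= age_completed_months(dob, survey_date) < 24:
            return age


def _simulate_child(
    rng: np.random.Generator,
    params: SyntheticParams,
    schedule: Schedule,
    child_id: str,
    stratum: str,
) -> tuple[ChildRecord, list[Visit], list[MOSVEvent]]:
    age_at_survey = _draw_age_days(rng, params.survey_date)
    dob = params.survey_date - dt.timedelta(days=age_at_survey)

    visit_ages: list[int] = []
    for target in params.visit_ages_days:
        if rng.random() < params.attendance_dropout:
            continue
        age = int(round(target + _truncated_jitter(rng, params.jitter_sd_days)))
        age = max(0, age)
        if age >= age_at_survey or age in visit_ages:
            continue
        visit_ages.append(age)
    visit_ages.sort()

    # --- administration pass --------------------------------------------
    receipt: dict[str, dt.date] = {}
    pending: set[str] = set()
    administered_at: dict[int, set[str]] = {}
    for age in visit_ages:
        date = dob + dt.timedelta(days=age)
        history = {n: d for n, d in receipt.items() if d < date}
        given: set[str] = set()
        for dose in schedule:
            if not eligible_for(dose, age, history, date, schedule):
                continue
            if dose.dose_name in pending:
                give = rng.random() < params.correction_prob
            else:
                give = rng.random() >= params.miss_prob_for(dose.dose_name, dose.summarized)
            if give:
                given.add(dose.dose_name)
                receipt[dose.dose_name] = date
                pending.discard(dose.dose_name)
            else:
                pending.add(dose.dose_name)
        if given:
            administered_at[age] = given

    visits = [
        Visit(
            date=dob + dt.timedelta(days=age),
            age_days=age,
            doses_administered=frozenset(doses),
        )
        for age, doses in sorted(administered_at.items())
    ]

    # --- truth pass over observable visits ------------------------------
    first_missed: dict[str, dt.date] = {}
    n_missed: dict[str, int] = {}
    for visit in visits:
        history = {n: d for n, d in receipt.items() if d < visit.date}
        for dose in schedule.summarized_doses:
            if not eligible_for(dose, visit.age_days, history, visit.date, schedule):
                continue
            if dose.dose_name in visit.doses_administered:
                continue
            first_missed.setdefault(dose.dose_name, visit.date)
            n_missed[dose.dose_name] = n_missed.get(dose.dose_name, 0) + 1
    events = []
    for dose_name, first_date in first_missed.items():
        got = receipt.get(dose_name)
        corrected = got is not None and got > first_date
        events.append(
            MOSVEvent(
                child_id=child_id,
                dose_name=dose_name,
                first_missed_date=first_date,
                n_missed_visits=n_missed[dose_name],
                corrected=corrected,
                correction_date=got if corrected else None,
                delay_days=(got - first_date).days if corrected else None,
            )
        )
    events.sort(key=lambda e: (e.first_missed_date, e.dose_name))

    # --- evidence --------------------------------------------------------
    card_seen = bool(rng.random() < params.card_prob)
    if card_seen:
        evidence = {
            name: DoseEvidence(EvidenceKind.DATE, date) for name, date in receipt.items()
        }
    else:
        evidence = {name: DoseEvidence(EvidenceKind.RECALL) for name in receipt}

    if params.weight_model == "EQUAL":
        weight = 1.0
    else:
        weight = float(rng.lognormal(0.0, params.weight_lognormal_sd))

    record = ChildRecord(
        child_id=child_id,
        survey_date=params.survey_date,
        card_seen=card_seen,
        weight=weight,
        stratum_id=stratum,
        cluster_id=f"{stratum}-{int(rng.integers(1, params.clusters_per_stratum + 1)):02d}",
        dob=dob,
        dob_year=dob.year,
        dob_month=dob.month,
        dob_day=dob.day,
        evidence=evidence,
    )
    return record, visits, events


def _corrupt_dates(
    rng: np.random.Generator,
    params: SyntheticParams,
    schedule: Schedule,
    record: ChildRecord,
    truth: SyntheticTruth,
) -> ChildRecord:
    if not record.card_seen or params.date_error_rate == 0:
        return record
    evidence = dict(record.evidence)
    for name in sorted(evidence):
        ev = evidence[name]
        if ev.kind is not EvidenceKind.DATE:
            continue
        if rng.random() >= params.date_error_rate:
            continue
        kind = rng.choice(["before_birth", "after_survey", "swap_within_series"])
        if kind == "swap_within_series":
            series = schedule[name].series_id if name in schedule else None
            partners = [
                d.dose_name
                for d in (schedule.series_doses(series) if series else [])
                if d.dose_name != name
                and evidence.get(d.dose_name, DoseEvidence()).kind is EvidenceKind.DATE
            ]
            if partners:
                other = partners[int(rng.integers(len(partners)))]
                evidence[name], evidence[other] = (
                    DoseEvidence(EvidenceKind.DATE, evidence[other].date),
                    DoseEvidence(EvidenceKind.DATE, evidence[name].date),
                )
                truth.anomalies.append((record.child_id, name, kind))
                continue
            kind = "before_birth"  # no swap partner: degrade to an absolute error
        if kind == "before_birth":
            bad = record.dob - dt.timedelta(days=int(rng.integers(1, 31)))
        else:
            bad = record.survey_date + dt.timedelta(days=int(rng.integers(1, 31)))
        evidence[name] = DoseEvidence(EvidenceKind.DATE, bad)
        truth.anomalies.append((record.child_id, name, kind))
    return replace(record, evidence=evidence)


def generate(
    params: SyntheticParams, schedule: Optional[Schedule] = None
) -> tuple[list[ChildRecord], SyntheticTruth]:
    """Generate a synthetic cohort and its ground-truth MOSV table.

    Deterministic given ``params.seed``.  Returns the child records (with
    any injected date errors applied) and a :class:`SyntheticTruth` holding,
    per child, the observable pre-corruption visits and the MOSV events a
    perfect detector would find on the uncorrupted record in crude mode.
    """
    schedule = schedule or builtin_schedule()
    rng = np.random.default_rng(params.seed)
    names = [s for s, _ in params.strata]
    props = np.array([p for _, p in params.strata], dtype=float)

    truth = SyntheticTruth()
    records: list[ChildRecord] = []
    width = len(str(params.n_children))
    for i in range(params.n_children):
        child_id = f"C{i + 1:0{width}d}"
        stratum = names[int(rng.choice(len(names), p=props))]
        record, visits, events = _simulate_child(rng, params, schedule, child_id, stratum)
        truth.visits[child_id] = visits
        truth.events[child_id] = events
        record = _corrupt_dates(rng, params, schedule, record, truth)
        records.append(record)
    return records, truth


def write_children_csv(
    records: Sequence[ChildRecord], path: str | Path, schedule: Optional[Schedule] = None
) -> Path:
    """Write records in the survey-ingest CSV dialect."""
    schedule = schedule or builtin_schedule()
    doses = schedule.dose_names
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "child_id": rec.child_id,
            "dob_year": rec.dob_year,
            "dob_month": rec.dob_month,
            "dob_day": rec.dob_day if rec.dob_day is not None else "",
            "survey_date": rec.survey_date.isoformat(),
            "card_seen": int(rec.card_seen),
            "weight": rec.weight,
            "stratum_id": rec.stratum_id,
            "cluster_id": rec.cluster_id,
        }
        for dose in doses:
            ev = rec.evidence_for(dose)
            if ev.kind is EvidenceKind.DATE:
                row[f"{dose}_date"] = ev.date.isoformat()
                row[f"{dose}_recall"] = 0
            elif ev.kind is EvidenceKind.TICK:
                row[f"{dose}_date"] = "tick"
                row[f"{dose}_recall"] = 0
            elif ev.kind is EvidenceKind.RECALL:
                row[f"{dose}_date"] = ""
                row[f"{dose}_recall"] = 1
            else:
                row[f"{dose}_date"] = ""
                row[f"{dose}_recall"] = 0
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_truth_csv(truth: SyntheticTruth, path: str | Path) -> Path:
    """Write the ground-truth event table as CSV."""
    rows = [
        {
            "child_id": e.child_id,
            "dose": e.dose_name,
            "first_missed_date": e.first_missed_date.isoformat(),
            "n_missed_visits": e.n_missed_visits,
            "corrected": int(e.corrected),
            "correction_date": e.correction_date.isoformat() if e.correction_date else "",
            "delay_days": e.delay_days if e.delay_days is not None else "",
        }
        for e in sorted(truth.all_events(), key=lambda e: (e.child_id, e.dose_name))
    ]
    path = Path(path)
    pd.DataFrame(
        rows,
        columns=[
            "child_id",
            "dose",
            "first_missed_date",
            "n_missed_visits",
            "corrected",
            "correction_date",
            "delay_days",
        ],
    ).to_csv(path, index=False)
    return path
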