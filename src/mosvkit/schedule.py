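"""Vaccination schedule representation and dose-eligibility queries.

A :class:`Schedule` is an ordered list of :class:`DoseDefinition` objects, one
per vaccine-dose (e.g. ``BCG``, ``DPT1``..``DPT3``).  Doses that belong to a
multi-dose series share a ``series_id`` and carry a ``dose_number``; eligibility
for dose *k* > 1 requires dose *k*-1 to have been received at least
``min_interval_days`` earlier.  Minimum ages, intervals and the optional
maximum age all live in configuration files, never in code: national schedules
differ and the WHO summary tables they come from are revised over time.

Ages are whole-day differences (``visit_date - dob``); all comparisons are
inclusive (``>=`` / ``<=``).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml

__all__ = [
    "DoseDefinition",
    "Schedule",
    "ScheduleError",
    "load_schedule",
    "builtin_schedule",
    "eligible_for",
]


class ScheduleError(ValueError):
    """Raised when a schedule configuration violates its invariants."""


@dataclass(frozen=True)
class DoseDefinition:
    """One vaccine-dose in the national calendar.

    Parameters
    ----------
    dose_name
        Unique name, e.g. ``"DPT1"``.
    series_id
        Series this dose belongs to (``"DPT"``), or ``None`` for standalone
        doses such as BCG.
    dose_number
        1-based position within the series (1 for standalone doses).
    min_age_days
        Earliest age (in days) at which the dose may be given.
    min_interval_days
        Minimum days since the previous dose in the series; 0 for the first
        dose of a series and for standalone doses.
    max_age_days
        Latest age at which the dose may be *offered* (e.g. the OPV birth
        dose); a documented dose given later still counts as received, the
        cap only stops eligibility (and hence MOSV detection).
    summarized
        Whether the dose enters MOSV summaries.  All dated doses still
        contribute to visit reconstruction.
    """

    dose_name: str
    series_id: Optional[str] = None
    dose_number: int = 1
    min_age_days: int = 0
    min_interval_days: int = 0
    max_age_days: Optional[int] = None
    summarized: bool = True
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.dose_number < 1:
            raise ScheduleError(f"{self.dose_name}: dose_number must be >= 1")
        if self.min_age_days < 0 or self.min_interval_days < 0:
            raise ScheduleError(f"{self.dose_name}: ages/intervals must be >= 0")
        first = self.dose_number == 1 or self.series_id is None
        if first and self.min_interval_days != 0:
            raise ScheduleError(
                f"{self.dose_name}: first-in-series/standalone dose must have "
                "min_interval_days = 0"
            )
        if not first and self.min_interval_days == 0:
            raise ScheduleError(
                f"{self.dose_name}: dose {self.dose_number} in series "
                f"{self.series_id} needs a positive min_interval_days"
            )
        if self.max_age_days is not None and self.max_age_days <= self.min_age_days:
            raise ScheduleError(
                f"{self.dose_name}: max_age_days must exceed min_age_days"
            )


@dataclass(frozen=True)
class Schedule:
    """An ordered, validated collection of dose definitions."""

    doses: tuple[DoseDefinition, ...]
    name: str = ""
    source_note: str = ""
    _by_name: Mapping[str, DoseDefinition] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        names = [d.dose_name for d in self.doses]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ScheduleError(f"duplicate dose_name(s): {sorted(dupes)}")
        by_series: dict[str, set[int]] = {}
        for d in self.doses:
            if d.series_id is not None:
                by_series.setdefault(d.series_id, set()).add(d.dose_number)
        for series, numbers in by_series.items():
            expected = set(range(1, max(numbers) + 1))
            missing = expected - numbers
            if missing:
                raise ScheduleError(
                    f"series {series!r} is missing dose(s) "
                    f"{sorted(missing)}: dose numbers must be contiguous from 1"
                )
        object.__setattr__(self, "_by_name", {d.dose_name: d for d in self.doses})

    def __iter__(self):
        return iter(self.doses)

    def __len__(self) -> int:
        return len(self.doses)

    def __getitem__(self, dose_name: str) -> DoseDefinition:
        return self._by_name[dose_name]

    def __contains__(self, dose_name: str) -> bool:
        return dose_name in self._by_name

    @property
    def dose_names(self) -> list[str]:
        return [d.dose_name for d in self.doses]

    @property
    def summarized_doses(self) -> list[DoseDefinition]:
        return [d for d in self.doses if d.summarized]

    def series_doses(self, series_id: str) -> list[DoseDefinition]:
        """Doses of one series ordered by dose_number."""
        out = [d for d in self.doses if d.series_id == series_id]
        return sorted(out, key=lambda d: d.dose_number)

    def previous_in_series(self, dose: DoseDefinition) -> Optional[DoseDefinition]:
        if dose.series_id is None or dose.dose_number == 1:
            return None
        for d in self.doses:
            if d.series_id == dose.series_id and d.dose_number == dose.dose_number - 1:
                return d
        return None  # unreachable for a validated Schedule

    def alias_map(self) -> dict[str, str]:
        """Map alternative column/dose names (e.g. Penta1) to canonical names."""
        out: dict[str, str] = {}
        for d in self.doses:
            for a in d.aliases:
                out[a] = d.dose_name
        return out

    def birth_doses(self) -> list[DoseDefinition]:
        """Doses schedulable from birth (min_age 0) — usable for dob imputation."""
        return [d for d in self.doses if d.min_age_days == 0]


def _parse_dose(raw: Mapping) -> DoseDefinition:
    try:
        return DoseDefinition(
            dose_name=str(raw["dose"]),
            series_id=raw.get("series"),
            dose_number=int(raw.get("number", 1)),
            min_age_days=int(raw.get("min_age_days", 0)),
            min_interval_days=int(raw.get("min_interval_days", 0)),
            max_age_days=(
                int(raw["max_age_days"]) if raw.get("max_age_days") is not None else None
            ),
            summarized=bool(raw.get("summarized", True)),
            aliases=tuple(raw.get("aliases", ()) or ()),
        )
    except KeyError as exc:  # pragma: no cover - config typo path
        raise ScheduleError(f"dose entry missing required field {exc}") from exc


def load_schedule(path: str | Path) -> Schedule:
    """Load and validate a schedule from a YAML/JSON configuration file.

    The file holds ``name``, ``source_note`` and a ``doses`` list of
    ``{dose, series, number, min_age_days, min_interval_days, max_age_days,
    summarized, aliases}`` mappings.  Raises :class:`ScheduleError` naming the
    offending dose or series on any invariant violation.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "doses" not in raw:
        raise ScheduleError(f"{path}: expected a mapping with a 'doses' list")
    doses = tuple(_parse_dose(entry) for entry in raw["doses"])
    return Schedule(
        doses=doses,
        name=str(raw.get("name", path.stem)),
        source_note=str(raw.get("source_note", "")),
    )


def builtin_schedule(profile: str = "epi_nigeria") -> Schedule:
    """Load one of the packaged schedule profiles.

    ``epi_nigeria``: eight classic EPI doses plus the OPV birth dose, MCV1
    from 270 days.  ``epi_colombia``: same infancy series with MMR1 from 365
    days standing in the MCV1 slot.
    """
    ref = resources.files("mosvkit.data") / f"{profile}.yaml"
    with resources.as_file(ref) as p:
        return load_schedule(p)


def eligible_for(
    dose: DoseDefinition,
    age_days: int,
    prior_receipt: Mapping[str, Optional[dt.date]],
    visit_date: dt.date,
    schedule: Optional[Schedule] = None,
) -> bool:
    """Is ``dose`` due for a child of ``age_days`` with this receipt history?

    ``prior_receipt`` maps dose names counted as received strictly before
    ``visit_date`` to their dates; a ``None`` date means "received, date
    unknown" (tick mark / recall) and is treated as preceding every dated
    visit, so it satisfies prerequisite and interval checks.

    Eligibility requires: the dose itself not yet received; age at or above
    the minimum; age at or below the maximum when one is set; and, for dose
    *k* > 1 of a series, dose *k*-1 received with the minimum interval elapsed.
    """
    if age_days < 0:
        raise ValueError("age_days must be >= 0")
    for name, d in prior_receipt.items():
        if d is not None and d >= visit_date:
            raise ValueError(
                f"prior_receipt[{name!r}] = {d} is not strictly before "
                f"visit_date {visit_date}"
            )
    if dose.dose_name in prior_receipt:
        return False
    if age_days < dose.min_age_days:
        return False
    if dose.max_age_days is not None and age_days > dose.max_age_days:
        return False
    if dose.series_id is not None and dose.dose_number > 1:
        if schedule is not None:
            prev = schedule.previous_in_series(dose)
            prev_name = prev.dose_name if prev else None
        else:
            # Conventional naming: strip the trailing number.
            prev_name = f"{dose.series_id}{dose.dose_number - 1}"
        if prev_name is None or prev_name not in prior_receipt:
            return False
        prev_date = prior_receipt[prev_name]
        if prev_date is not None:
            if (visit_date - prev_date).days < dose.min_interval_days:
                return False
    return True
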