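"""End-to-end analysis run: ingest, clean, select, detect, aggregate, export.

:func:`run_analysis` wires the pipeline together and writes every output
table as CSV with fixed sort orders and 4-decimal float formatting, so a
re-run of the same configuration byte-reproduces its outputs.  All
randomness lives in the synthetic generator; the analysis path is fully
deterministic.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .core import Mode, detect_mosvs
from .indicators import IndicatorTable, stratified_run
from .ingest import (
    ChildRecord,
    ColumnMap,
    clean_dates,
    impute_birth_day,
    read_children,
    select_cohort,
)
from .schedule import Schedule, builtin_schedule, load_schedule

__all__ = ["RunConfig", "ReportingError", "run_analysis", "prepare_cohort"]

log = logging.getLogger("mosvkit")

FLOAT_FORMAT = "%.4f"


class ReportingError(RuntimeError):
    """A named pipeline stage failed; the stage is in ``.stage``."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run.

    ``mode`` may be ``"CRUDE"``, ``"VALID"`` or ``"BOTH"``; with ``BOTH``
    the two accountings run over the identical cleaned cohort.  The strata
    spec maps reporting strata to lists of ``stratum_id`` values and may be
    given inline or as a YAML file path.
    """

    input_path: str | Path
    out_dir: str | Path
    schedule_path: Optional[str | Path] = None
    schedule_profile: str = "epi_nigeria"
    mode: str = "BOTH"
    strata_spec: Optional[Mapping[str, Sequence[str]] | str | Path] = None
    age_window_months: tuple[int, int] = (12, 24)
    column_map: ColumnMap = field(default_factory=ColumnMap)

    def modes(self) -> list[Mode]:
        m = self.mode.upper()
        if m == "BOTH":
            return [Mode.CRUDE, Mode.VALID]
        return [Mode(m)]


def _load_strata_spec(spec) -> Optional[dict[str, list[str]]]:
    if spec is None or isinstance(spec, Mapping):
        return dict(spec) if spec is not None else None
    with open(spec) as fh:
        raw = yaml.safe_load(fh)
    return {str(k): [str(v) for v in vs] for k, vs in raw.items()}


def prepare_cohort(
    records: Sequence[ChildRecord],
    schedule: Schedule,
    age_window_months: tuple[int, int] = (12, 24),
):
    """Impute birth days, clean dates, and select the analysis cohort."""
    prepared = [clean_dates(impute_birth_day(rec, schedule), schedule) for rec in records]
    return select_cohort(prepared, age_window_months)


def _write_csv(df: pd.DataFrame, path: Path, sort_by: Sequence[str]) -> None:
    df = df.sort_values(list(sort_by), kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _events_frame(cohort, schedule, mode: Mode) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        for e in detect_mosvs(rec, schedule, mode):
            rows.append(
                {
                    "child_id": e.child_id,
                    "dose": e.dose_name,
                    "mode": mode.value,
                    "first_missed_date": e.first_missed_date.isoformat(),
                    "n_missed_visits": e.n_missed_visits,
                    "corrected": int(e.corrected),
                    "correction_date": (
                        e.correction_date.isoformat() if e.correction_date else ""
                    ),
                    "delay_days": e.delay_days if e.delay_days is not None else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "child_id",
            "dose",
            "mode",
            "first_missed_date",
            "n_missed_visits",
            "corrected",
            "correction_date",
            "delay_days",
        ],
    )


def run_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the full MOSV analysis and export all tables.

    Writes, under ``config.out_dir``: the cohort-selection log, the
    event-level table, the visit-based, child-based, coverage and delay
    tables (per mode, per stratum and overall), the delay ECDFs, and a run
    manifest echoing the configuration and counts.  Returns the written
    paths keyed by table name.  Failures raise :class:`ReportingError`
    naming the stage (schedule, ingest, cohort, indicators, export).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        if config.schedule_path is not None:
            schedule = load_schedule(config.schedule_path)
        else:
            schedule = builtin_schedule(config.schedule_profile)
    except Exception as exc:
        raise ReportingError("schedule", str(exc)) from exc

    try:
        dialect = dataclasses.replace(
            config.column_map,
            aliases={**schedule.alias_map(), **dict(config.column_map.aliases)},
        )
        records = read_children(config.input_path, dialect)
    except Exception as exc:
        raise ReportingError("ingest", str(exc)) from exc

    try:
        selection = prepare_cohort(records, schedule, config.age_window_months)
        strata_spec = _load_strata_spec(config.strata_spec)
    except Exception as exc:
        raise ReportingError("cohort", str(exc)) from exc
    log.info(
        "cohort: %d input, %d included", selection.n_input, len(selection.included)
    )

    paths: dict[str, Path] = {}
    paths["cohort"] = out_dir / "cohort_selection.csv"
    selection.to_frame().to_csv(paths["cohort"], index=False)

    tables: dict[Mode, IndicatorTable] = {}
    event_frames = []
    try:
        for mode in config.modes():
            tables[mode] = stratified_run(
                selection.included, schedule, mode, strata_spec
            )
            event_frames.append(_events_frame(selection.included, schedule, mode))
    except Exception as exc:
        raise ReportingError("indicators", str(exc)) from exc

    try:
        paths["events"] = out_dir / "events.csv"
        _write_csv(
            pd.concat(event_frames, ignore_index=True),
            paths["events"],
            ["mode", "child_id", "dose"],
        )
        merged: dict[str, list[pd.DataFrame]] = {}
        for mode, table in tables.items():
            for name, frame in table.frames().items():
                merged.setdefault(name, []).append(frame)
        sort_keys = {
            "vb": ["stratum", "mode", "indicator", "dose"],
            "cb": ["stratum", "mode", "indicator", "dose", "component"],
            "coverage": ["stratum", "mode", "dose"],
            "delay": ["stratum", "mode", "dose"],
            "ecdf": ["stratum", "mode", "dose", "delay_days"],
        }
        for name, frames in merged.items():
            paths[name] = out_dir / f"{name}.csv"
            _write_csv(pd.concat(frames, ignore_index=True), paths[name], sort_keys[name])

        manifest = {
            "software": {"name": "mosvkit", "version": __version__},
            "run_date": dt.date.today().isoformat(),
            "config": {
                "input_path": str(config.input_path),
                "schedule": schedule.name,
                "mode": config.mode,
                "age_window_months": list(config.age_window_months),
                "strata_spec": strata_spec,
            },
            "counts": {
                "input": selection.n_input,
                "included": len(selection.included),
                "excluded_no_card": selection.excluded_no_card,
                "excluded_no_dob": selection.excluded_no_dob,
                "excluded_age": selection.excluded_age,
                "excluded_no_dates": selection.excluded_no_dates,
            },
        }
        paths["manifest"] = out_dir / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except ReportingError:
        raise
    except Exception as exc:
        raise ReportingError("export", str(exc)) from exc
    return paths
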