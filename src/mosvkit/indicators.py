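"""Visit-based and child-based MOSV indicators, coverage impact, delays.

Visit-based (VB) indicators share the denominator "visits at which the child
was eligible for the dose(s)":

* VB1 — proportion of dose-eligible visits with a MOSV for that dose;
* VB2 — proportion of vaccine-eligible visits with at least one MOSV;
* VB3 — mean number of MOSVs per vaccine-eligible visit, and its inverse,
  read as the number of vaccination visits between MOSVs.

Child-based (CB) indicators:

* CB1 — proportion of children (among those with at least one dose-eligible
  visit) who experienced at least one MOSV for the dose, split by whether it
  was corrected by survey time;
* CB2 — proportion of children with at least one MOSV for any summarized
  dose, split by whether all, some or none of their MOSVs were corrected.

Point estimates carry child-level survey weights (a visit inherits its
child's weight); unweighted counts are always reported alongside.  No
variance estimation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import (
    Mode,
    MOSVEvent,
    annotate_visits,
    counterfactual_receipt,
    dose_accounting,
    detect_mosvs,
)
from .ingest import ChildRecord
from .schedule import Schedule

__all__ = [
    "Ratio",
    "VisitBasedResult",
    "ChildBasedResult",
    "CoverageComparison",
    "DelayDistribution",
    "IndicatorTable",
    "visit_based",
    "child_based",
    "potential_coverage",
    "time_to_correction",
    "stratified_run",
]

ANY_DOSE = "ANY"
DELAY_PERCENTILES = (25, 50, 75, 90)
SMALL_N_THRESHOLD = 25  # distributions below this are flagged, not suppressed


@dataclass(frozen=True)
class Ratio:
    """A weighted and unweighted numerator/denominator pair."""

    num_w: float = 0.0
    den_w: float = 0.0
    num_n: int = 0
    den_n: int = 0

    @property
    def weighted(self) -> Optional[float]:
        return self.num_w / self.den_w if self.den_w > 0 else None

    @property
    def unweighted(self) -> Optional[float]:
        return self.num_n / self.den_n if self.den_n > 0 else None

    def add(self, amount_w: float, in_numerator: bool) -> "Ratio":
        return Ratio(
            self.num_w + (amount_w if in_numerator else 0.0),
            self.den_w + amount_w,
            self.num_n + (1 if in_numerator else 0),
            self.den_n + 1,
        )


def _annotations(children, schedule, mode):
    return [(rec, annotate_visits(rec, schedule, mode)) for rec in children]


@dataclass
class VisitBasedResult:
    mode: Mode
    vb1: dict[str, Ratio]
    vb2: Ratio
    vb3: Ratio  # numerator counts MOSVs, may exceed the denominator

    @property
    def vb3_inverse_weighted(self) -> Optional[float]:
        v = self.vb3.weighted
        return None if v in (None, 0) else 1.0 / v

    @property
    def vb3_inverse_unweighted(self) -> Optional[float]:
        v = self.vb3.unweighted
        return None if v in (None, 0) else 1.0 / v

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for dose in sorted(self.vb1):
            r = self.vb1[dose]
            rows.append(("VB1", dose, r.num_n, r.den_n, r.unweighted, r.weighted))
        rows.append(
            ("VB2", ANY_DOSE, self.vb2.num_n, self.vb2.den_n, self.vb2.unweighted, self.vb2.weighted)
        )
        rows.append(
            ("VB3", ANY_DOSE, self.vb3.num_n, self.vb3.den_n, self.vb3.unweighted, self.vb3.weighted)
        )
        rows.append(
            (
                "VB3_inverse",
                ANY_DOSE,
                self.vb3.den_n,
                self.vb3.num_n,
                self.vb3_inverse_unweighted,
                self.vb3_inverse_weighted,
            )
        )
        return pd.DataFrame(
            rows, columns=["indicator", "dose", "numerator", "denominator", "unweighted", "weighted"]
        )


def visit_based(
    children: Sequence[ChildRecord],
    schedule: Schedule,
    mode: Mode = Mode.CRUDE,
) -> VisitBasedResult:
    """Compute VB1 per summarized dose and overall VB2/VB3.

    Denominators are visits at which the child was eligible for the dose
    (VB1) or for at least one summarized dose (VB2, VB3); a visit carries its
    child's survey weight.  Zero-denominator proportions are ``None``.
    """
    vb1 = {d.dose_name: Ratio() for d in schedule.summarized_doses}
    vb2 = Ratio()
    vb3_num_w, vb3_num_n = 0.0, 0
    for rec, anns in _annotations(children, schedule, mode):
        w = rec.weight
        for ann in anns:
            for dose in ann.eligible:
                vb1[dose] = vb1[dose].add(w, dose in ann.missed)
            if ann.eligible:
                vb2 = vb2.add(w, bool(ann.missed))
                vb3_num_w += w * len(ann.missed)
                vb3_num_n += len(ann.missed)
    vb3 = Ratio(vb3_num_w, vb2.den_w, vb3_num_n, vb2.den_n)
    return VisitBasedResult(mode=Mode(mode), vb1=vb1, vb2=vb2, vb3=vb3)


@dataclass
class ChildBasedResult:
    mode: Mode
    cb1: dict[str, dict[str, Ratio]]  # dose -> {any, corrected, uncorrected}
    cb2: dict[str, Ratio]  # {any, all_corrected, some_corrected, none_corrected}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for dose in sorted(self.cb1):
            for component, r in self.cb1[dose].items():
                rows.append(
                    ("CB1", dose, component, r.num_n, r.den_n, r.unweighted, r.weighted)
                )
        for component, r in self.cb2.items():
            rows.append(("CB2", ANY_DOSE, component, r.num_n, r.den_n, r.unweighted, r.weighted))
        return pd.DataFrame(
            rows,
            columns=[
                "indicator",
                "dose",
                "component",
                "numerator",
                "denominator",
                "unweighted",
                "weighted",
            ],
        )


def child_based(
    children: Sequence[ChildRecord],
    schedule: Schedule,
    mode: Mode = Mode.CRUDE,
    events: Optional[Mapping[str, Sequence[MOSVEvent]]] = None,
) -> ChildBasedResult:
    """Compute CB1 per dose (corrected/uncorrected split) and overall CB2.

    ``events`` may supply precomputed per-child event lists (keyed by
    child_id) from :func:`mosvkit.core.detect_mosvs`; otherwise they are
    detected here.  The CB1 denominator for a dose is the children with at
    least one visit at which they were eligible for that dose; the CB2
    denominator is children with at least one vaccine-eligible visit.
    """
    doses = [d.dose_name for d in schedule.summarized_doses]
    cb1 = {d: {k: Ratio() for k in ("any", "corrected", "uncorrected")} for d in doses}
    cb2 = {k: Ratio() for k in ("any", "all_corrected", "some_corrected", "none_corrected")}

    for rec, anns in _annotations(children, schedule, mode):
        if events is not None:
            evs = list(events.get(rec.child_id, ()))
        else:
            evs = detect_mosvs(rec, schedule, mode)
        by_dose = {e.dose_name: e for e in evs}
        ever_eligible = set().union(*(ann.eligible for ann in anns)) if anns else set()
        w = rec.weight
        for dose in doses:
            if dose not in ever_eligible:
                continue
            e = by_dose.get(dose)
            cb1[dose]["any"] = cb1[dose]["any"].add(w, e is not None)
            cb1[dose]["corrected"] = cb1[dose]["corrected"].add(w, e is not None and e.corrected)
            cb1[dose]["uncorrected"] = cb1[dose]["uncorrected"].add(
                w, e is not None and not e.corrected
            )
        if ever_eligible:
            has_event = bool(evs)
            n_corr = sum(e.corrected for e in evs)
            cb2["any"] = cb2["any"].add(w, has_event)
            cb2["all_corrected"] = cb2["all_corrected"].add(w, has_event and n_corr == len(evs))
            cb2["none_corrected"] = cb2["none_corrected"].add(w, has_event and n_corr == 0)
            cb2["some_corrected"] = cb2["some_corrected"].add(
                w, has_event and 0 < n_corr < len(evs)
            )
    return ChildBasedResult(mode=Mode(mode), cb1=cb1, cb2=cb2)


@dataclass(frozen=True)
class CoverageComparison:
    """Observed vs counterfactual ("no MOSVs") coverage for one dose."""

    dose_name: str
    mode: Mode
    observed: Ratio
    potential: Ratio

    @property
    def difference_weighted(self) -> Optional[float]:
        o, p = self.observed.weighted, self.potential.weighted
        return None if o is None or p is None else p - o


def potential_coverage(
    children: Sequence[ChildRecord],
    schedule: Schedule,
    mode: Mode = Mode.CRUDE,
) -> list[CoverageComparison]:
    """Observed coverage and the coverage achievable with no MOSVs.

    The counterfactual walk credits every summarized dose the child was
    eligible for at each attended visit, assuming all previously due doses
    had also been given.  Observed coverage counts any positive evidence
    under ``CRUDE`` (dates, ticks, recall) and only counted valid doses under
    ``VALID``.  Potential coverage counts a child as covered if they are
    observed-covered or the counterfactual walk credits the dose, so it can
    never fall below the observed estimate.
    """
    mode = Mode(mode)
    doses = [d.dose_name for d in schedule.summarized_doses]
    obs = {d: Ratio() for d in doses}
    pot = {d: Ratio() for d in doses}
    for rec in children:
        if mode is Mode.CRUDE:
            observed_set = {n for n, ev in rec.evidence.items() if ev.received}
        else:
            observed_set = set(dose_accounting(rec, schedule, mode).counted_receipt)
        cf = counterfactual_receipt(rec, schedule)
        w = rec.weight
        for dose in doses:
            covered = dose in observed_set
            obs[dose] = obs[dose].add(w, covered)
            pot[dose] = pot[dose].add(w, covered or dose in cf)
    return [
        CoverageComparison(dose_name=d, mode=mode, observed=obs[d], potential=pot[d])
        for d in doses
    ]


@dataclass
class DelayDistribution:
    """Empirical distribution of days from first missed visit to correction."""

    dose_name: str
    n_corrected: int
    ecdf: list[tuple[int, float]]
    quantiles: dict[int, Optional[int]]
    small_n: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.dose_name, d, f, self.n_corrected) for d, f in self.ecdf],
            columns=["dose", "delay_days", "cum_fraction", "n"],
        )


def time_to_correction(
    events: Iterable[MOSVEvent], dose: str
) -> DelayDistribution:
    """Unweighted ECDF and quantiles of time-to-correction for one dose.

    Quantiles use the inverse-ECDF rule (lowest delay whose cumulative
    fraction reaches the percentile).  Distributions built on fewer than 25
    corrected events are flagged ``small_n`` — mirroring survey practice of
    masking sparse panels — but still reported.
    """
    delays = sorted(
        e.delay_days for e in events if e.dose_name == dose and e.corrected
    )
    n = len(delays)
    if n == 0:
        return DelayDistribution(dose, 0, [], {p: None for p in DELAY_PERCENTILES}, True)
    ecdf: list[tuple[int, float]] = []
    seen = 0
    for d in sorted(set(delays)):
        seen += delays.count(d)
        ecdf.append((d, seen / n))
    quantiles = {}
    for p in DELAY_PERCENTILES:
        idx = next(i for i, (_, f) in enumerate(ecdf) if f >= p / 100)
        quantiles[p] = ecdf[idx][0]
    return DelayDistribution(dose, n, ecdf, quantiles, n < SMALL_N_THRESHOLD)


@dataclass
class StratumResult:
    stratum: str
    n_children: int
    visit_based: VisitBasedResult
    child_based: ChildBasedResult
    coverage: list[CoverageComparison]
    delays: dict[str, DelayDistribution]
    events: list[MOSVEvent]


@dataclass
class IndicatorTable:
    """All indicators for one mode, per stratum and overall."""

    mode: Mode
    overall: StratumResult
    strata: dict[str, StratumResult] = field(default_factory=dict)

    def frames(self) -> dict[str, pd.DataFrame]:
        """Tidy DataFrames (vb, cb, coverage, delay, ecdf) across strata."""
        vb, cb, cov, delay, ecdf = [], [], [], [], []
        for name, res in [("overall", self.overall), *sorted(self.strata.items())]:
            f = res.visit_based.to_frame()
            f.insert(0, "stratum", name)
            vb.append(f)
            f = res.child_based.to_frame()
            f.insert(0, "stratum", name)
            cb.append(f)
            for c in res.coverage:
                cov.append(
                    (
                        name,
                        c.dose_name,
                        c.observed.unweighted,
                        c.observed.weighted,
                        c.potential.unweighted,
                        c.potential.weighted,
                        c.difference_weighted,
                    )
                )
            for dose, dd in sorted(res.delays.items()):
                delay.append(
                    (
                        name,
                        dose,
                        dd.n_corrected,
                        dd.quantiles[25],
                        dd.quantiles[50],
                        dd.quantiles[75],
                        dd.quantiles[90],
                        dd.small_n,
                    )
                )
                f = dd.to_frame()
                if not f.empty:
                    f.insert(0, "stratum", name)
                    ecdf.append(f)
        out = {
            "vb": pd.concat(vb, ignore_index=True),
            "cb": pd.concat(cb, ignore_index=True),
            "coverage": pd.DataFrame(
                cov,
                columns=[
                    "stratum",
                    "dose",
                    "observed_unweighted",
                    "observed_weighted",
                    "potential_unweighted",
                    "potential_weighted",
                    "difference_weighted",
                ],
            ),
            "delay": pd.DataFrame(
                delay,
                columns=["stratum", "dose", "n_corrected", "p25", "p50", "p75", "p90", "small_n"],
            ),
            "ecdf": (
                pd.concat(ecdf, ignore_index=True)
                if ecdf
                else pd.DataFrame(columns=["stratum", "dose", "delay_days", "cum_fraction", "n"])
            ),
        }
        for f in out.values():
            f.insert(1, "mode", self.mode.value)
        return out


def _compute_stratum(name, children, schedule, mode) -> StratumResult:
    events: list[MOSVEvent] = []
    by_child: dict[str, list[MOSVEvent]] = {}
    for rec in children:
        evs = detect_mosvs(rec, schedule, mode)
        events.extend(evs)
        by_child[rec.child_id] = evs
    delays = {
        d.dose_name: time_to_correction(events, d.dose_name)
        for d in schedule.summarized_doses
    }
    return StratumResult(
        stratum=name,
        n_children=len(children),
        visit_based=visit_based(children, schedule, mode),
        child_based=child_based(children, schedule, mode, events=by_child),
        coverage=potential_coverage(children, schedule, mode),
        delays=delays,
        events=events,
    )


def stratified_run(
    children: Sequence[ChildRecord],
    schedule: Schedule,
    mode: Mode = Mode.CRUDE,
    strata_spec: Optional[Mapping[str, Sequence[str]]] = None,
) -> IndicatorTable:
    """Compute every indicator overall and per stratum.

    ``strata_spec`` maps reporting strata to lists of ``stratum_id`` values,
    allowing super-strata (e.g. a "north" made of several regions).  When
    omitted, each distinct ``stratum_id`` forms its own stratum.  Children
    whose ``stratum_id`` appears in no super-stratum are excluded from the
    stratified comparison but always contribute to the overall results.
    Referencing a ``stratum_id`` absent from the data raises ``KeyError``.
    """
    mode = Mode(mode)
    children = list(children)
    present = {rec.stratum_id for rec in children}
    if strata_spec is None:
        strata_spec = {s: [s] for s in sorted(present)}
    else:
        unknown = {
            sid for ids in strata_spec.values() for sid in ids if sid not in present
        }
        if unknown:
            raise KeyError(f"strata spec references unknown stratum_id(s) {sorted(unknown)}")
    table = IndicatorTable(
        mode=mode, overall=_compute_stratum("overall", children, schedule, mode)
    )
    for name, ids in strata_spec.items():
        members = [rec for rec in children if rec.stratum_id in set(ids)]
        table.strata[name] = _compute_stratum(name, members, schedule, mode)
    return table
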