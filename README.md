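# mosvkit

Missed opportunities for simultaneous vaccination (MOSV) from child-level
vaccination-date records.

A MOSV occurs when a child attends a vaccination visit and receives some,
but not all, of the vaccine-doses they are eligible for that day — for
example a first DPT dose at six weeks without the OPV dose recommended at
the same age. Household coverage surveys (DHS, MICS, EPI surveys) that
transcribe vaccination dates from home-based records make these events
visible at population scale: every dated dose marks a visit, and the
national schedule determines what else was due. `mosvkit` is for
epidemiologists and immunization-programme analysts who want standardized,
reproducible MOSV indicators from such survey tables.

## What it computes

From a child-level CSV (dates of birth and vaccination, card-seen flag,
survey weights, strata) and a schedule configuration (minimum ages,
minimum intervals, optional maximum ages per dose), the package:

1. **reconstructs visits** — one per distinct vaccination date on the card;
2. **detects MOSVs** under two dose accountings:
   *crude* (any dated dose counts as received) and *valid* (doses given too
   early or after too short an interval are invalid; a later administration
   may fill an earlier slot of the series, so a documented DPT2 can count
   as DPT1);
3. **aggregates indicators**, survey-weighted and unweighted:
   - visit-based: VB1 = P(MOSV for dose *d* | visit eligible for *d*),
     VB2 = P(≥1 MOSV | vaccine-eligible visit), VB3 = mean MOSVs per
     eligible visit, and 1/VB3 = visits between MOSVs;
   - child-based: CB1 = P(≥1 MOSV for dose *d*), CB2 = P(≥1 MOSV for any
     dose), each split by whether the missed doses were later *corrected*
     (received by survey time);
   - **achievable coverage**: the counterfactual coverage per dose had every
     eligible dose been given at every attended visit, versus observed;
   - **time to correction**: ECDF and 25/50/75/90th percentiles of days from
     the first missed opportunity to eventual receipt (panels with n < 25
     are flagged as small).

Data cleaning follows survey practice: missing birth days are imputed from
a same-month birth dose (else the first of the month), and nonsensical dates
(before birth, after the interview, out of order or duplicated within a
series) are demoted to tick marks so the child keeps credit for the dose
while the bad date stays out of the visit reconstruction.

A synthetic cohort generator (`mosvkit.synthetic`) emulates the structure of
a DHS child recode — 12–23-month cohort, partial card availability, visits
anchored on the recommended ages, injected per-visit miss events with later
corrections, and date-recording errors — with a known ground-truth event
table, so the whole pipeline is testable without registration-gated survey
data.

## Worked example

```python
from mosvkit import (Mode, SyntheticParams, builtin_schedule, generate,
                     visit_based, child_based)
from mosvkit.reporting import prepare_cohort

schedule = builtin_schedule("epi_nigeria")   # BCG, OPV0-3, DPT1-3, MCV1
records, truth = generate(SyntheticParams(n_children=2000, seed=99), schedule)
cohort = prepare_cohort(records, schedule).included

vb = visit_based(cohort, schedule, Mode.CRUDE)
cb = child_based(cohort, schedule, Mode.CRUDE)
print(f"VB2 {vb.vb2.weighted:.1%}  VB3 {vb.vb3.weighted:.3f}  "
      f"CB2 {cb.cb2['any'].weighted:.1%}")
```

prints

```
VB2 29.0%  VB3 0.309  CB2 62.9%
```

meaning 29.0% of vaccine-eligible visits produced at least one MOSV, an
eligible visit produced 0.309 MOSVs on average (one MOSV every ~3.2
visits), and 62.9% of children experienced at least one. The narrative
scripts in `examples/` walk through each capability — eligibility queries,
crude-vs-valid detection with slot reallocation, truth recovery from the
generator's CSV, the full indicator set, and a stratified end-to-end run
exporting tidy CSV tables (`examples/05_full_run.py` shows, e.g., observed
valid DPT3 coverage of 36.9% against an achievable 56.9% in a
high-miss-rate synthetic world).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

generates a 2000-child synthetic survey, writes it in the ingest CSV
dialect, and runs the complete analysis — ingestion, cleaning, cohort
selection, MOSV detection in both modes, stratified indicator tables,
coverage comparison and delay distributions — before writing its JSON
output. It is the same end-to-end path the test suite verifies against a
brute-force eligibility oracle and the generator's ground truth.

## Layout

- `src/mosvkit/schedule.py` — schedule model, config loading, eligibility
- `src/mosvkit/ingest.py` — CSV contract, birth-day imputation, date
  cleaning, cohort filters
- `src/mosvkit/core.py` — visits, crude/valid accounting, MOSV detection
- `src/mosvkit/indicators.py` — VB/CB indicators, achievable coverage,
  delay distributions, stratification
- `src/mosvkit/synthetic.py` — DHS-like generator with ground truth
- `src/mosvkit/reporting.py` — end-to-end runs and deterministic CSV export
- `docs/methods.md` — model, assumptions, parameter defaults, limitations
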