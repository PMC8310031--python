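# Methods

## The measurement problem

Home-based vaccination records transcribed in household surveys give, for
each child, a set of dated dose administrations. Every distinct date is a
*visit*: a contact with vaccination services at which any other due dose
could, in principle, have been given. A missed opportunity for simultaneous
vaccination (MOSV) is a (visit, dose) pair where the dose was due — by age,
series position and interval — but not administered. `mosvkit` reconstructs
these visits, detects MOSVs, and summarizes their frequency and their
consequences for coverage and timeliness.

## Eligibility model

A dose *d* is due for a child at a visit on date *t* when all of:

1. *d* has not already been received (counted) strictly before *t*;
2. age(*t*) ≥ `min_age_days(d)`;
3. age(*t*) ≤ `max_age_days(d)` when a cap is configured (e.g. the OPV
   birth dose, offered only through day 13);
4. for dose *k* > 1 of a series, dose *k*−1 was received strictly before
   *t* and *t* − date(*k*−1) ≥ `min_interval_days(d)`.

Ages are whole-day differences `t − dob`; all comparisons are inclusive and
no grace period is applied. The age cap affects eligibility (and hence MOSV
detection) only — a documented dose given past its cap still counts as
received. Schedule constants live entirely in configuration; the packaged
profiles use BCG/OPV0 from birth (OPV0 capped at 13 days), OPV1/DPT1 from
42 days, 28-day intra-series intervals, and a measles-containing dose from
270 days (Nigeria profile) or 365 days (Colombia profile, MMR). Penta dose
columns alias onto the DPT series. One-, two- and three-dose series are
supported; boosters beyond the third dose are out of scope.

## Crude versus valid dose accounting

The two accountings differ only in which *received* doses count, never in
visit eligibility (otherwise schedule-compliant visits would be flagged):

- **crude** — every dated dose counts as itself, regardless of timing. This
  matches how most immunization programmes actually operate: early doses
  are almost never re-administered.
- **valid** — per series, administered dated doses are scanned in date
  order and fill dose slots 1, 2, 3 in turn; a dose fills the next open
  slot only if the child met that slot's minimum age and the minimum
  interval since the previously counted dose. Doses that fill no slot are
  invalid; an administered second dose may count as the first. Standalone
  doses are validated on age alone. Under this accounting, later visits at
  which the still-open slot could have been filled become MOSVs, and a
  "correction" means a counted (valid) administration of the slot exists at
  a later date, including via reallocation.

## Evidence without dates

Tick marks, illegible dates and caregiver recall assert receipt without a
usable date. Such doses receive credit: they are never counted as missed,
they generate no events, and they satisfy series prerequisites as if
received before every dated visit (an undated receipt cannot be placed, and
penalizing the child in either direction would manufacture or suppress
events on no evidence). They do not, however, fill valid-dose slots — their
timing cannot be verified — and consequently do not count toward observed
*valid* coverage, while they do count toward observed crude coverage and
they seed the counterfactual receipt map in both modes. This assumption is
the one place where undated evidence shapes series logic; it is flagged
here for sensitivity analysis.

## Cleaning and cohort selection

Date cleaning runs two fixed passes: absolute checks first (dates before
birth or after the interview), then series-order checks in dose-number
order, demoting any dose dated on or before the last retained date of its
series (out-of-order if earlier, duplicate if equal) and continuing against
the last *retained* date — keeping the maximal consistent prefix. Demoted
dates become tick marks with a reason flag, so credit is preserved and
cleaning is idempotent and total.

Missing birth days are imputed from a dated birth dose (minimum age 0)
falling inside the reported birth month — earliest if several — else as the
first of the month. Restricting to the birth month guarantees that no
vaccination date can precede the imputed birth date; a birth dose dated in
a later month is real but uninformative about the birth day.

The analysis cohort is: card seen, birth month and year known, age at
survey in [12, 24) completed months, and at least one retained vaccination
date. Exclusions are tallied in that order, each child once. Excluded
children are dropped from all MOSV outputs rather than treated as MOSV-free.

## Indicators

Visit-based indicators use vaccine-eligible visits as denominator: VB1 (per
dose), VB2 (any dose), VB3 (mean MOSVs per eligible visit; its inverse is
the expected number of visits between MOSVs). Child-based indicators use
children with at least one eligible visit for the dose (CB1) or for any
dose (CB2); each splits by correction status, and the splits sum exactly to
the headline proportion by construction. One event is recorded per (child,
dose), dated at the first missed visit, with the number of missing visits
alongside — child-based rates and time-to-correction both refer to the
first opportunity.

Point estimates carry child-level survey weights (a visit inherits its
child's weight); unweighted counts are always reported alongside, and with
equal weights the two coincide exactly. No confidence intervals or design
effects are computed: MOSV summaries are descriptive, and the intended use
is broad-stroke comparison across strata and survey rounds.

Achievable ("potential") coverage re-walks each child's visits crediting
every summarized dose due under the counterfactual history, assuming all
previously due doses had also been given; credits granted at a visit do not
unlock further doses that same day (intervals run from strictly earlier
receipts). A child counts as potentially covered if the walk credits the
dose *or* they are observed-covered under the active accounting — the union
guarantees potential ≥ observed even for, e.g., a crude-counted early dose
with no subsequent visit.

Time-to-correction distributions are unweighted ECDFs over corrected
events' delays; quantiles use the inverse-ECDF (type-1) rule — the smallest
delay whose cumulative fraction reaches the percentile — chosen for exact
reproducibility on small n. Distributions with fewer than 25 corrected
events are flagged `small_n` (reported, not suppressed). Stratified runs
accept super-strata (unions of stratum ids); children in no super-stratum
contribute to overall results only.

## Synthetic cohort generator

The generator states a survey world and reports its own ground truth.
Children are aged uniformly so that completed months at interview lie in
[12, 24). Visits are schedule-anchored — targets default to days 0, 42, 70,
98 and 270 — with normal jitter (sd 7 days, truncated at ±21) and a 0.1
per-visit skip probability; a Poisson contact process was rejected because
anchored visits make eligible-visit denominators predictable. At each
attended visit every eligible dose is administered unless a miss event
fires (default probability 0.15 per summarized dose); a previously missed
dose is given at each later eligible visit with the catch-up probability
(default 0.5). Defaults for card availability (0.6; national values range
roughly 0.2–0.85) and the miss/catch-up rates were chosen once to land
visit-level MOSV frequencies in the 15–40% band typical of published
national estimates, and are not tuned thereafter. 2% of recorded dates are
corrupted (before-birth, after-survey, within-series swap, equal shares).
Weights are equal by default or lognormal on request.

A visit at which every due dose was missed administers nothing, leaves no
card entry, and is therefore invisible to any date-based detector; the
generator drops such visits and records truth misses only at observable
visits. Missed doses cascade: a missed DPT1 blocks DPT2 eligibility until
corrected, so downstream expectations must account for it. The truth table
equals what a perfect crude-mode detector would find on the uncorrupted
record; with no injected date errors the full CSV pipeline reproduces it
event-for-event, which is what a green truth-recovery test establishes —
and all it establishes: the generator does not emulate real-data features
like digit-preference in dates, missing birth days, caregiver recall error
or card-retention bias correlated with utilization.

One derived consequence used by the parameter-recovery tests: the per-visit
miss probability of a dose equals the injected *p* at first offerings but
1 − catch-up probability at retries, so recovering *p* from VB1 presumes
catch-up = 1 − *p*; the tests set it so.

## Numerical and degenerate-input choices

Zero-denominator proportions are reported as null with their zero counts.
VB3's inverse is null when VB3 = 0. Events are ordered by (first missed
date, dose name); exported CSVs are sorted on fixed keys and floats written
to 4 decimals, so identical configurations byte-reproduce their outputs.
All randomness is confined to the generator; the analysis path is
deterministic. Children interviewed on or before their (imputed) birth date
are routed to the no-birth-date exclusion.

## Known limitations

Results describe card-holders only; where cards are scarce the cohort may
over-represent service users. Dates that are wrong but not nonsensical pass
cleaning undetected. Non-vaccination health contacts (curative care) are
invisible to date-based reconstruction, so these are missed opportunities
at *vaccination* visits only. Whether reference implementations apply a
grace period to minimum ages/intervals is unknown; none is applied here,
so valid-dose figures may run slightly strict.
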