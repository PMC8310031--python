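"""Detect missed opportunities for one child, crude vs valid accounting.

The child's card shows a first DPT dose at four weeks — before the 42-day
minimum age — then DPT2 at ten weeks and DPT3 later.  Under crude accounting
all three doses count as given.  Under valid-dose accounting the early first
dose is discounted, DPT2 fills the first slot, DPT3 the second, and the
child is still owed a third valid dose — so later visits where it could have
been given become missed opportunities.
"""

import datetime as dt

from mosvkit import (
    INVALID,
    ChildRecord,
    DoseEvidence,
    EvidenceKind,
    Mode,
    builtin_schedule,
    detect_mosvs,
    reallocate_valid_doses,
)

schedule = builtin_schedule("epi_nigeria")
dob = dt.date(2017, 3, 1)


def at(days):
    return DoseEvidence(EvidenceKind.DATE, dob + dt.timedelta(days=days))


child = ChildRecord(
    child_id="demo",
    survey_date=dt.date(2018, 6, 1),
    card_seen=True,
    weight=1.0,
    dob=dob,
    evidence={
        "BCG": at(0), "OPV1": at(42), "OPV2": at(70), "OPV3": at(100),
        "DPT1": at(28), "DPT2": at(70), "DPT3": at(100), "MCV1": at(280),
    },
)

acct = reallocate_valid_doses(child, schedule)
print("valid-dose reallocation (administered -> counted):")
for label in ("DPT1", "DPT2", "DPT3"):
    target = acct.reallocation[label]
    print(f"  {label} -> {target if target != INVALID else 'INVALID (too early)'}")

for mode in (Mode.CRUDE, Mode.VALID):
    events = detect_mosvs(child, schedule, mode)
    print(f"\n{mode.value} mode: {len(events)} MOSV event(s)")
    for e in events:
        status = f"corrected after {e.delay_days} d" if e.corrected else "never corrected"
        print(f"  {e.dose_name}: first missed at age "
              f"{(e.first_missed_date - dob).days} d over {e.n_missed_visits} visit(s), {status}")
print("\nValid mode flags the visits where the missing third valid DPT dose"
      " could have been repeated; crude mode sees a fully vaccinated child.")
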