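"""Load a vaccination schedule and ask which doses are due at a visit.

Builds the packaged Nigeria-style EPI profile and queries eligibility for a
ten-week-old child who received BCG at birth and a first DPT/OPV round at
six weeks.
"""

import datetime as dt

from mosvkit import builtin_schedule, eligible_for

schedule = builtin_schedule("epi_nigeria")
print(f"schedule '{schedule.name}': {len(schedule)} doses, "
      f"{len(schedule.summarized_doses)} summarized")

dob = dt.date(2017, 3, 1)
visit = dob + dt.timedelta(days=70)
history = {  # received strictly before the visit
    "BCG": dob,
    "DPT1": dob + dt.timedelta(days=42),
    "OPV1": dob + dt.timedelta(days=42),
}

print(f"\nvisit at age 70 days, history: {sorted(history)}")
for dose in schedule:
    due = eligible_for(dose, 70, history, visit, schedule)
    print(f"  {dose.dose_name:5s} due: {due}")
print("\nDPT2/OPV2 are due (age 70 >= 70, interval 28 >= 28); MCV1 is not"
      " (first dose at 270 days); OPV0 aged out at 13 days.")
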