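# Classic EPI infancy schedule, Nigeria-style profile.
# Minimum ages/intervals transcribed from the WHO recommended-schedule
# summary tables; MCV1 at 9 months (270 days).  Penta doses alias onto the
# DPT series for survey rounds that report pentavalent vaccine.
name: epi_nigeria
source_note: >-
  Eight classic EPI doses (BCG, OPV1-3, DPT1-3, MCV1) plus the OPV birth
  dose; WHO recommended ages, Nigeria measles timing.
doses:
  - {dose: BCG, series: null, number: 1, min_age_days: 0, min_interval_days: 0, summarized: true}
  - {dose: OPV0, series: null, number: 1, min_age_days: 0, min_interval_days: 0, max_age_days: 13, summarized: false}
  - {dose: OPV1, series: OPV, number: 1, min_age_days: 42, min_interval_days: 0, summarized: true}
  - {dose: OPV2, series: OPV, number: 2, min_age_days: 70, min_interval_days: 28, summarized: true}
  - {dose: OPV3, series: OPV, number: 3, min_age_days: 98, min_interval_days: 28, summarized: true}
  - {dose: DPT1, series: DPT, number: 1, min_age_days: 42, min_interval_days: 0, summarized: true, aliases: [PENTA1]}
  - {dose: DPT2, series: DPT, number: 2, min_age_days: 70, min_interval_days: 28, summarized: true, aliases: [PENTA2]}
  - {dose: DPT3, series: DPT, number: 3, min_age_days: 98, min_interval_days: 28, summarized: true, aliases: [PENTA3]}
  - {dose: MCV1, series: null, number: 1, min_age_days: 270, min_interval_days: 0, summarized: true, aliases: [MEASLES1]}
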