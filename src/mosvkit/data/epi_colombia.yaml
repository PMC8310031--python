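# Classic EPI infancy schedule, Colombia-style profile: identical infancy
# series but the measles-containing dose is MMR at 12 months (365 days).
name: epi_colombia
source_note: >-
  Eight classic EPI doses with MMR1 (365 days) as the measles-containing
  dose; WHO recommended ages.
doses:
  - {dose: BCG, series: null, number: 1, min_age_days: 0, min_interval_days: 0, summarized: true}
  - {dose: OPV1, series: OPV, number: 1, min_age_days: 42, min_interval_days: 0, summarized: true}
  - {dose: OPV2, series: OPV, number: 2, min_age_days: 70, min_interval_days: 28, summarized: true}
  - {dose: OPV3, series: OPV, number: 3, min_age_days: 98, min_interval_days: 28, summarized: true}
  - {dose: DPT1, series: DPT, number: 1, min_age_days: 42, min_interval_days: 0, summarized: true, aliases: [PENTA1]}
  - {dose: DPT2, series: DPT, number: 2, min_age_days: 70, min_interval_days: 28, summarized: true, aliases: [PENTA2]}
  - {dose: DPT3, series: DPT, number: 3, min_age_days: 98, min_interval_days: 28, summarized: true, aliases: [PENTA3]}
  - {dose: MCV1, series: null, number: 1, min_age_days: 365, min_interval_days: 0, summarized: true, aliases: [MMR1, MEASLES1]}
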