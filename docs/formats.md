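# File formats

All artifacts are UTF-8 text. Tables are CSV with an explicit header row;
event streams are JSON Lines; reports are JSON. Missing values are empty
fields. Every writer in `prospmatch.io` round-trips through its reader.

## patients.csv

One row per patient.

| column | type | notes |
|---|---|---|
| patient_id | str | unique within a cohort |
| facility_id | str | |
| age | float | years, ≥ 18 |
| race | str | `black`, `white`, `other_or_missing` |
| female | bool | |
| advance_directive | bool | |
| dementia | bool | |
| n_hospitalizations | int | prior year, ≥ 0 |
| any_hospitalization | bool | == (n_hospitalizations > 0) |
| can_score | float | 0–99 |
| jfi_score | float | 0–13 |
| excluded | bool | hospice/palliative/institutionalized |
| transferred | bool | generator's arm designation |
| latent_transfer_propensity | float | generator-internal, never used in matching |

## visits.csv

`patient_id` (str), `day` (int, offset from the exposure start; pre-exposure
days are negative), `clinic` (`treatment_clinic` or `usual_clinic`).

## eligibility.csv

`patient_id`, `arm` (`treated_eligible` / `control_eligible` / `ineligible`),
`reason` (nonempty when ineligible), `pull_index` (0-based pull at first
satisfaction; empty if not pull-based).

## pools.csv

One row per (treated, candidate) pair: `treated_id`, `control_id`,
`distance` (float ≥ 0), `tier` (1-based), `rank_within_tier` (1-based),
`eligible_for_recruitment` (bool, pool-level), `pull_index`. A treated
patient with an empty pool appears as a single row with empty candidate
columns.

## dyads.csv

`treated_id`, `control_id`, `tier_of_enrollment`, `days_between_enrollments`
(7 × week lag), `distance`.

## events.jsonl

One JSON object per line with keys `week` (int), `kind` (one of
`pull_opened`, `letter_sent`, `contact_attempt`, `enrolled_treated`,
`enrolled_control`, `dyad_formed`, `escalation`, `window_closed`),
`treated_id`, `control_id`, `tier`, `distance` (null where not applicable).
The log replays deterministically to the dyad list
(`prospmatch.dyads_from_log`).

## balance.csv

One row per covariate: `covariate`, `kind` (`continuous`/`binary`),
`group1_stat`/`group1_spread` (mean/SD, or count/proportion for binary),
`group2_stat`/`group2_spread`, `smd` (full precision), `n_missing_group1`,
`n_missing_group2`, `imbalanced` (|SMD| ≥ 0.2), `warning` (undefined SMD).
Group 1 is the treated arm.

## report.json

Written by `run_full_study`: cohort and eligibility counts, `pull_schedule`,
`pool_statistics`, `recruitment` summary (dyad count, matched fraction,
tier-of-enrollment percentages, median days between enrollments, cumulative
weekly tier counts), and the pre/post balance tables as record lists.
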