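# Data dictionary

Five UTF-8 CSV files with a header row, ISO-8601 dates (`YYYY-MM-DD`),
booleans as `0`/`1`, and empty string for absent optional values.  Rows
are written sorted by primary id.  The layout is a deliberately
simplified claims-extract schema, not a bit-faithful CMS RIF dialect.

## beneficiaries.csv

| column | type | description |
|---|---|---|
| `bene_id` | string, primary key | opaque beneficiary identifier |
| `birth_year` | integer | year of birth |
| `sex` | `F` / `M` | |
| `race` | string | coded category (default set: `white`, `black`, `hispanic`, `other`; configurable) |
| `state` | 2-letter code | state of residence |
| `county_id` | string | county identifier; joins `county_chi.csv` (comparison-state rows use `<ST>_pool`) |
| `ffs_flag` | 0/1 | fee-for-service coverage |
| `enrolled_months` | 24-char string of 0/1 | monthly enrollment flags, Jan 2011 – Dec 2012; continuous enrollment = all `1` |

## inpatient.csv

One row per facility stay (hospital, SNF, or hospice).

| column | type | description |
|---|---|---|
| `claim_id` | string, primary key | |
| `bene_id` | string | beneficiary reference |
| `facility_id` | string | |
| `facility_type` | `hospital` / `snf` / `hospice` | |
| `admit_date`, `discharge_date` | date | inclusive; `admit_date <= discharge_date` |
| `drg_code` | string | required for hospital stays; may be empty otherwise |
| `admission_source` | `routine` / `transfer_hospital` / `transfer_snf` / `transfer_hospice` / `unknown` | |
| `through_ed` | 0/1 | admitted through the emergency department |
| `discharge_disposition` | `home` / `home_health` / `snf` / `hospice` / `transfer_hospital` / `expired` / `other` | |

## ed_visits.csv

| column | type | description |
|---|---|---|
| `visit_id` | string, primary key | |
| `bene_id` | string | |
| `visit_date` | date | |
| `disposition` | `discharged` / `admitted` | `admitted` iff `linked_claim_id` present |
| `linked_claim_id` | string, optional | resulting inpatient claim |

## drg_weights.csv

| column | type | description |
|---|---|---|
| `drg_code` | string, primary key | |
| `weight` | float in [0.1, 30.0] | service-intensity relative weight |

## county_chi.csv

| column | type | description |
|---|---|---|
| `county_id` | string, primary key | |
| `chi_score` | float in [1, 100] | community-hardship (storm impact) score |
| `quartile` | `Q1`–`Q4` | must be consistent with the score bins (Q1 ≤ 39 < Q2 ≤ 47 < Q3 ≤ 58 < Q4) |

## Derived outputs

`transfers.csv` (from transfer linkage): `bene_id`, `source_type`
(`hospital`/`snf`/`hospice`), `source_claim_id` (empty when a coded
transfer has no matching stay on file), `hospital_claim_id`,
`detection_rule` (`source_code` / `date_overlap`).
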