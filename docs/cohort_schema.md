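# Cohort file schema (version 1)

Comma-separated UTF-8 text, header row, one respondent per row. The same
dictionary is available programmatically as
`healthineq.cohort.COLUMN_DICTIONARY`.

| column | type | description |
|---|---|---|
| `srh` | int | self-rated health, ordinal 1 (very bad) … 5 (very good) |
| `income_initial` | float | per-capita household income, currency units/year, ≥ 0 |
| `premium` | float | insurance premium actually paid, currency units/year, ≥ 0 |
| `oop_spend` | float | out-of-pocket medical spending, currency units/year, ≥ 0 |
| `reimbursement` | float | insurance reimbursement received, 0 ≤ value ≤ `oop_spend` |
| `outpatient_visits` | int | outpatient visits in the year, ≥ 0 |
| `inpatient_episodes` | int | inpatient episodes in the year, ≥ 0 |
| `gender` | int | 1 = female, 0 = male |
| `age` | int | age in years |
| `education_years` | int | completed years of schooling |
| `education_group` | str | `below_middle_school` / `middle_school` / `high_school` / `above_high_school` |
| `marital` | int | 1 = married, 0 = not married |
| `urban` | int | 1 = urban resident, 0 = rural |
| `region` | str | `east` / `central` / `west` |

Validation (applied on both read and write) rejects a missing mandatory
column, an SRH value outside 1–5, negative money or count fields,
reimbursement exceeding out-of-pocket spending, and unknown
`region`/`education_group` levels, naming the offending column and row.

The four insurance-stage income vectors are derived, not stored:

- contribution = `income_initial` − `premium`
- treatment = contribution − `oop_spend`
- reimbursement stage = treatment + `reimbursement`
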