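# Dataset column dictionary

All tables are plain CSV. Dates are ISO `YYYY-MM-DD`; flags are 0/1
integers; paid amounts are 2020 USD with two decimals.

## enrollment.csv
| column | type | meaning |
|---|---|---|
| patient_id | str | patient key |
| span_start | date | first covered day of the enrollment span |
| span_end | date | last covered day of the span (inclusive) |
| dual_eligible | 0/1 | span carries simultaneous Medicare eligibility |

## pharmacy.csv
| column | type | meaning |
|---|---|---|
| patient_id | str | patient key |
| drug | str | human-readable product name |
| fill_date | date | dispensing date |
| days_supply | int >= 1 | days of drug supplied |
| paid | float | paid amount |
| is_oaap | 0/1 | oral atypical antipsychotic |
| is_typical_ap | 0/1 | first-generation antipsychotic |
| is_lai | 0/1 | long-acting injectable antipsychotic |

## medical.csv
| column | type | meaning |
|---|---|---|
| patient_id | str | patient key |
| setting | str | `inpatient`, `ed`, or `outpatient` |
| service_date | date | service date (admission date for inpatient) |
| admit_date | date or empty | inpatient admission date |
| discharge_date | date or empty | inpatient discharge date (inclusive) |
| paid | float | paid amount |
| dx1..dx4 | str or empty | ICD-10 diagnosis codes, any position |

## patients.csv
| column | type | meaning |
|---|---|---|
| patient_id | str | patient key |
| birth_date | date | date of birth |
| sex | str | `M` / `F` |
| race_ethnicity | str | Black, White, Hispanic, Other, Unknown |

## ground_truth.csv (generator output only)
| column | type | meaning |
|---|---|---|
| patient_id | str | patient key |
| true_covered_day_count | int | OAAP-covered days outside hospital, days 0..364 |
| true_hospital_day_count | int | hospital days within 0..364 |
| true_pdc | float | covered / (365 - hospital days), capped at 1 |
| true_pattern | str | persistent / discontinued / switched / augmented |
| passes_inclusion | 0/1 | meets all seven inclusion criteria |
| failing_criterion | str | first failing criterion label, empty if none |
| is_edge_case | 0/1 | hand-built boundary fixture |
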