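# apclaims

Claims-based analysis of oral atypical antipsychotic (OAAP) treatment
patterns for patients with schizophrenia: incident-user cohort selection,
hospitalization-adjusted proportion-of-days-covered (PDC) adherence,
switch/augmentation classification, Quan-Charlson comorbidity scoring, and
all-cause vs. schizophrenia-related utilization/expenditure aggregation.
A bundled synthetic claims generator with per-patient ground-truth labels
makes the whole pipeline testable without any external data.

## Pipeline

Five stages, each reading/writing plain CSV tables in a directory
(column dictionary in `src/apclaims/resources/schema.md`):

```bash
apclaims simulate  --n-patients 2000 --seed 7 --out data/ --edge-cases
apclaims cohort    --in data/ --out data/      # cohort.csv, attrition.csv
apclaims adherence --in data/ --out data/      # exposure.csv
apclaims hru       --in data/ --out data/      # utilization.csv, expenditures.csv
apclaims report    --in data/ --out report/    # table1..table4 + attrition
```

`simulate` also accepts a YAML/JSON config (`--config cfg.yaml`) covering
the drug mix, per-patient refill-persistence behaviour, switch/augment/LAI
probabilities, hospitalization and visit rates, lognormal cost parameters,
demographics and diagnosis-coding model.

### Key conventions

- Day arithmetic is index-anchored: index fill = day 0, baseline is days
  -182..-1, follow-up days 0..364.
- Coverage is the union of fill intervals per drug (no stockpiling shift);
  a day covered by several products counts once in "all-OAAP" totals.
- PDC = covered days outside hospital / (365 - hospital days), capped at 1;
  adherent means PDC >= 0.8 (closed bound).
- Switch: another OAAP dispensed within the half-open window (E, E+30]
  after the index drug's last covered day E, with no index refill on or
  after that dispensing. Augmentation: index refilled and another OAAP
  overlapping the index coverage >= 60 days.
- Inpatient stays merge claims that share a day; LOS is inclusive
  (discharge - admission + 1). ED visits collapse per service date;
  outpatient visits count claim rows.
- Schizophrenia-related scope: claims carrying an F20-prefix diagnosis in
  any position; the schizophrenia-related drug bucket is OAAP fills.

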