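# mmlot

Claims-based analysis of multiple-myeloma treatment patterns and economic
burden, implemented as a reusable, testable pipeline:

1. **`mmlot.synthetic_claims`** — seeded generator of French-claims-style
   per-patient claims streams (drug dispensings, hospital stays, diagnoses, outpatient
   cost items, vital status) with retained ground-truth labels (true line
   -of-therapy trajectory, transplant status, eligibility verdict), so every
   downstream stage can be scored without access to any real data.
2. **`mmlot.cohort_builder`** — diagnosis confirmation (two-record rule),
   index-date setting, eligibility rules with first-failure reporting,
   follow-up determination (death / 12-month claim gap / end of
   observation), stem-cell-transplant detection from DRG/CCAM codes, and
   Charlson comorbidity scoring from ICD-10 claims.
3. **`mmlot.lot_engine`** — segmentation of dispensing streams into numbered
   lines of therapy using a 28-day regimen window, per-drug grace periods,
   a 90-day discontinuation gap, and a 40-day overlap criterion; regimen
   backbone labelling; descriptive and Kaplan–Meier duration estimation.
4. **`mmlot.cost_engine`** — cost ledger construction with price
   annualisation, PPPY/PPPM rates (365.25-day years, 30.4375-day months),
   treatment-administration and disease-related attribution flags,
   event-of-interest hospitalisation accounting, and report-shaped cost
   tables stratified by transplant status and line of therapy.
5. **`mmlot.reporting`** — baseline characteristics table, attrition
   waterfall, per-line regimen frequencies, and end-to-end orchestration
   with a JSON run manifest.

All code lists that drive classification (diagnosis prefixes, transplant
DRG/CCAM codes, event-of-interest codes, malignancy exclusions) and all
algorithm parameters (windows, gaps, grace periods, age rule) are
configuration with documented defaults — see `mmlot.config`.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis) and a brute-force
line-of-therapy segmentation oracle (`tests/_oracle.py`) that the production
engine is checked against, exhaustively on small grids and by seeded
sampling on larger ones.  `tests/test_acceptance.py` holds one test per
acceptance criterion.

## CLI

```sh
# generate a synthetic claims set (five CSVs + ground_truth.csv)
mmlot simulate --seed 7 --n-patients 500 --out run/

# run everything on those claims
mmlot all --in run/claims --out run/out

# or simulate + analyse in one go (config optional)
mmlot all --config config.yaml --seed 7 --out run/out

# individual stages write their output subset
mmlot cohort|lots|costs|report --in run/claims --out run/out
```

The config file is a single YAML/JSON document with one section per module
(`study_window`, `code_lists`, `eligibility`, `lot`, `cost`,
`regimen_precedence`, `simulate`); every key is optional.  JSON schemas are
available from `mmlot.config.config_json_schema()` and
`mmlot.synthetic_claims.sim_config_json_schema()`.

Outputs are plain CSV (cohort, follow-up, exclusion log, lots, KM curves,
all-cause cost table, treatment-administration costs by line, event-of-
interest summary, baseline table, regimen frequencies, attrition waterfall)
plus `manifest.json` recording the config hash, seed, input digests and row
counts.  Identical config + seed reproduce byte-identical tables.

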