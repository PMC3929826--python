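# clinicflow

Discrete-event simulation of patient flow through a multi-class outpatient
clinic with scheduled physician servers, plus the statistical pipeline
around it: distribution fitting from event logs, model validation against
observed waits, what-if scenario analysis over staffing/schedule changes,
and a 2:2:1 weighted waiting-time score for ranking scenarios.

The modeled clinic has six stations (registration, cash desk, novice
residents, an experienced resident, a senior staff physician, paraclinic
services). Patients arrive during an admission window with truncated-normal
interarrival gaps, pass registration and cash, see a class-dependent first
physician, may be referred for a senior-staff consult and/or paraclinic
services, and leave. Physicians start seeing patients only at their
attendance time, so queue waits decompose into a *before-attendance* and an
*after-attendance* component. Ten scenarios (extra residents, earlier
attendance, later admission, and combinations) are compared against the
base case over 1000 seeded replications with common random numbers.

## Command line

```bash
clinicflow generate --n 375 --seed 7 --out checklist.csv   # synthetic event log
clinicflow fit --log checklist.csv                          # distribution fits
clinicflow simulate --scenario 9 --seed 1 --out day.csv     # one clinic day
clinicflow compare --base 0 --scenarios 1-10 --reps 1000 --seed 42 --out-prefix results
clinicflow validate --observed src/clinicflow/data/observed_station_waits.csv --reps 1000
```

`compare` writes a decomposed-waits table (per-server before/after/total,
one column per scenario) and a weighted-score table, and prints the best
scenario with its percent reduction versus the base case.

## Library layout

| module | contents |
| --- | --- |
| `clinicflow.clinic_model` | domain types (`ClinicConfig`, `Station`, `DistributionSpec`, ...), YAML config I/O, the base-case parameterization |
| `clinicflow.des_engine` | event-calendar simulation core, wait decomposition, event-log CSV I/O |
| `clinicflow.scenarios` | the ten scenarios as data (field-path deltas), `apply_scenario` |
| `clinicflow.estimation` | interarrival/service fitting, Wald–Wolfowitz runs test, validation against observed summaries |
| `clinicflow.replication_stats` | replication runs, weighted mean, percent reduction, ranking, calibration |
| `clinicflow.synthetic_data` | engine-backed synthetic checklist generator and observed-summary builder |
| `clinicflow.datasets` | bundled reference tables (published waits, observed station summaries) |

Bundled configuration files live in `src/clinicflow/configs/`:
`base_case.yaml` (with calibrated mix/routing parameters — reproduce them
with `python scripts/calibrate_base.py`), `scenario_1.yaml` ...
`scenario_10.yaml`, and `scenarios.yaml` (the delta definitions).

The patient-class mix, consult/paraclinic routing probabilities and the
admission-window length are not published; they are calibrated by seeded
random search (`replication_stats.calibrate`) so that simulated base-case
per-station waits match the reference values, and the calibrated set ships
in `base_case.yaml`.

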