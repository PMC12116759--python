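# Trajectory-table column dictionary

The long hourly table has one row per patient-hour. `patient_id` and
`hour` identify the row; every other column is aggregated within the hour
as listed (doses are summed, measurements averaged) when raw timestamps
are binned.

## Hourly columns (`trajectories` table)

| column | units | aggregation | description |
|---|---|---|---|
| patient_id | — | key | stable patient identifier |
| hour | h | key | hours since ICU admission (re-indexed to the first glucose measurement by the pipeline) |
| glucose | mg/dL | mean | blood glucose; NaN before the first measurement |
| insulin | units | sum | regular insulin administered during the hour (the action) |
| sofa | score 0–20 | mean | Sequential Organ Failure Assessment severity score |
| on_vasopressor | 0/1 | mean | any vasopressor running |
| vasopressor_dose | µg/kg/min | mean | norepinephrine-equivalent rate |
| on_ventilator | 0/1 | mean | invasive mechanical ventilation |
| heart_rate | bpm | mean | |
| map_mmhg | mmHg | mean | mean arterial pressure |
| resp_rate | /min | mean | respiratory rate |
| temp_c | °C | mean | core temperature |
| spo2 | % | mean | oxygen saturation |
| creatinine | mg/dL | mean | |
| lactate | mmol/L | mean | (dropped by the >30% missingness rule at default rates) |
| hemoglobin | g/dL | mean | |
| potassium | mEq/L | mean | |
| wbc | 10⁹/L | mean | white-cell count |

## Static columns (`patients` table)

| column | units | description |
|---|---|---|
| age | years | |
| male | 0/1 | |
| weight | kg | |
| bmi | kg/m² | |
| diabetes_type1 / diabetes_type2 | 0/1 | |
| surgery_cabg / surgery_valve | 0/1 | procedure type (not exclusive) |
| chf, copd, esrd, hypertension, prior_mi | 0/1 | comorbidities |
| elixhauser | score | comorbidity index |
| died_within_24h | 0/1 | exclusion flag |
| ambiguous_meds | 0/1 | exclusion flag: dose/timing unresolvable |
| no_early_glucose | 0/1 | exclusion flag: no glucose in hours 0–2 |
| other_short_acting_insulin | 0/1 | exclusion flag: aspart/lispro/NPH/70-30 exposure |
| first_glucose_hour | h | hour of the first glucose measurement |
| `_true_*` | — | simulator ground-truth parameters (drive, sensitivity, baseline); never used as features |

## Engineered state features (added by the pipeline)

| column | definition |
|---|---|
| glucose_lag1..4 | prior hourly glucose; pre-admission lags backfilled with the first observed value |
| glucose_delta1..4 | hourly changes within the 4-h window (`delta_k = lag_{k-1} - lag_k`) |
| glucose_insulin_ratio | `delta1 / max(previous hour's insulin, 0.1)` |
| hour_idx | hour index since first glucose (normalized copy of `hour`) |
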