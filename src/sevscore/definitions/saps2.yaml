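# SAPS II, transcribed from the published point table. Worst values in the
# first 24 ICU hours. The PaO2/FiO2 component applies only to ventilated
# (or CPAP) patients. Chronic disease takes the single worst qualifying
# comorbidity; admission type contributes medical 6, unscheduled surgical 8,
# scheduled surgical 0. Predicted mortality uses the published logistic
# transform logit(p) = -7.7631 + 0.0737*S + 0.9971*ln(S + 1).
name: SAPS2
family: icu
default_window: icu_24h_worst
provenance: transcribed
band_tables:
  heart_rate:
    - [-.inf, 40, 11]
    - [40, 70, 2]
    - [70, 120, 0]
    - [120, 160, 4]
    - [160, .inf, 7]
  sbp:
    - [-.inf, 70, 13]
    - [70, 100, 5]
    - [100, 200, 0]
    - [200, .inf, 2]
  temperature:
    - [-.inf, 39.0, 0]
    - [39.0, .inf, 3]
  pf_ratio:  # PaO2/FiO2 (mmHg), ventilated or CPAP only
    - [-.inf, 100, 11]
    - [100, 200, 9]
    - [200, .inf, 6]
  urine_output_24h:
    - [-.inf, 500, 11]
    - [500, 1000, 4]
    - [1000, .inf, 0]
  bun:
    - [-.inf, 28, 0]
    - [28, 84, 6]
    - [84, .inf, 10]
  wbc:
    - [-.inf, 1.0, 12]
    - [1.0, 20.0, 0]
    - [20.0, .inf, 3]
  potassium:
    - [-.inf, 3.0, 3]
    - [3.0, 5.0, 0]
    - [5.0, .inf, 3]
  sodium:
    - [-.inf, 125, 5]
    - [125, 145, 0]
    - [145, .inf, 1]
  bicarbonate:
    - [-.inf, 15, 6]
    - [15, 20, 3]
    - [20, .inf, 0]
  bilirubin:
    - [-.inf, 4.0, 0]
    - [4.0, 6.0, 4]
    - [6.0, .inf, 9]
  gcs_total:
    - [-.inf, 6, 26]
    - [6, 9, 13]
    - [9, 11, 7]
    - [11, 14, 5]
    - [14, .inf, 0]
age_bands:
  - [-.inf, 40, 0]
  - [40, 60, 7]
  - [60, 70, 12]
  - [70, 75, 15]
  - [75, 80, 16]
  - [80, .inf, 18]
chronic_flag_points:
  aids: 17
  hematologic_malignancy: 10
  metastatic_cancer: 9
chronic_flag_mode: max
admission_type_points:
  medical: 6
  unscheduled_surgical: 8
  scheduled_surgical: 0
special:
  pf_ratio_if_ventilated: true
mortality_transform:
  intercept: -7.7631
  slope: 0.0737
  log_slope: 0.9971   # * ln(score + 1)
required_variables: [heart_rate, sbp, temperature, gcs_total, sodium,
                     potassium, bicarbonate, wbc, bun, urine_output_24h]
impute_normal_variables: [bilirubin]
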