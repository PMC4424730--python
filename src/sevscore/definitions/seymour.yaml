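# Seymour pre-hospital critical-illness score, additive point form over the
# published variable set (age, systolic blood pressure, respiratory rate,
# heart rate, pulse oximetry, GCS), evaluated on triage vitals. The point
# bands below are this package's documented operationalization (synthetic
# stand-in for the original publication's coefficients, which are not
# redistributable here): 0 points at normal physiology, graded points at
# conventional pre-hospital derangement thresholds.
name: SEYMOUR
family: ed
default_window: ed_triage
provenance: operationalized
band_tables:
  sbp:
    - [-.inf, 90, 3]
    - [90, 100, 2]
    - [100, 110, 1]
    - [110, .inf, 0]
  respiratory_rate:
    - [-.inf, 10, 2]
    - [10, 22, 0]
    - [22, 30, 1]
    - [30, .inf, 2]
  heart_rate:
    - [-.inf, 50, 1]
    - [50, 110, 0]
    - [110, 140, 1]
    - [140, .inf, 2]
  spo2:
    - [-.inf, 90, 3]
    - [90, 95, 1]
    - [95, .inf, 0]
  gcs_total:
    - [-.inf, 9, 4]
    - [9, 13, 2]
    - [13, 15, 1]
    - [15, .inf, 0]
age_bands:
  - [-.inf, 45, 0]
  - [45, 65, 1]
  - [65, .inf, 2]
required_variables: [sbp, respiratory_rate, heart_rate, spo2, gcs_total]
impute_normal_variables: []
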