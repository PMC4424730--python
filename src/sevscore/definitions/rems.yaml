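# Rapid Emergency Medicine Score (REMS), systolic-blood-pressure variant.
# Physiology bands transcribed from the published REMS table (APACHE II-style
# 0-4 point bands); the SBP bands are this package's documented mapping of the
# published mean-arterial-pressure bands onto systolic pressure (the variant
# substitutes SBP for MAP because SBP is more often recorded at triage).
# Temperature bands follow the APACHE II table from which REMS descends.
name: REMS
family: ed
default_window: ed_worst
provenance: transcribed  # sbp + temperature bands: operationalized
band_tables:
  heart_rate:
    - [-.inf, 40, 4]
    - [40, 55, 3]
    - [55, 70, 2]
    - [70, 110, 0]
    - [110, 140, 2]
    - [140, 180, 3]
    - [180, .inf, 4]
  respiratory_rate:
    - [-.inf, 6, 4]
    - [6, 10, 2]
    - [10, 12, 1]
    - [12, 25, 0]
    - [25, 35, 1]
    - [35, 50, 3]
    - [50, .inf, 4]
  sbp:
    - [-.inf, 70, 4]
    - [70, 90, 2]
    - [90, 150, 0]
    - [150, 180, 2]
    - [180, 220, 3]
    - [220, .inf, 4]
  temperature:
    - [-.inf, 30.0, 4]
    - [30.0, 32.0, 3]
    - [32.0, 34.0, 2]
    - [34.0, 36.0, 1]
    - [36.0, 38.5, 0]
    - [38.5, 39.0, 1]
    - [39.0, 41.0, 3]
    - [41.0, .inf, 4]
  spo2:
    - [-.inf, 75, 4]
    - [75, 86, 3]
    - [86, 90, 1]
    - [90, .inf, 0]
  gcs_total:
    - [-.inf, 5, 4]
    - [5, 8, 3]
    - [8, 11, 2]
    - [11, 14, 1]
    - [14, .inf, 0]
age_bands:
  - [-.inf, 45, 0]
  - [45, 55, 2]
  - [55, 65, 3]
  - [65, 75, 5]
  - [75, .inf, 6]
required_variables: [heart_rate, respiratory_rate, sbp, temperature, spo2, gcs_total]
impute_normal_variables: []
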