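# Modified Early Warning Score (MEWS), transcribed from the published table.
# The neurologic (AVPU) component is derived from the Glasgow Coma Scale total
# via a fixed mapping: 15 -> Alert (0), 13-14 -> Voice (1), 9-12 -> Pain (2),
# <=8 -> Unresponsive (3).
name: MEWS
family: ed
default_window: ed_worst
provenance: transcribed
band_tables:
  heart_rate:
    - [-.inf, 41, 2]
    - [41, 51, 1]
    - [51, 101, 0]
    - [101, 111, 1]
    - [111, 130, 2]
    - [130, .inf, 3]
  respiratory_rate:
    - [-.inf, 9, 2]
    - [9, 15, 0]
    - [15, 21, 1]
    - [21, 30, 2]
    - [30, .inf, 3]
  sbp:
    - [-.inf, 71, 3]
    - [71, 81, 2]
    - [81, 101, 1]
    - [101, 200, 0]
    - [200, .inf, 2]
  temperature:
    - [-.inf, 35.0, 2]
    - [35.0, 38.5, 0]
    - [38.5, .inf, 2]
  gcs_total:  # AVPU derived from GCS
    - [-.inf, 9, 3]
    - [9, 13, 2]
    - [13, 15, 1]
    - [15, .inf, 0]
required_variables: [heart_rate, respiratory_rate, sbp, temperature, gcs_total]
impute_normal_variables: []
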