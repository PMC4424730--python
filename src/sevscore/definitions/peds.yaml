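# Prince of Wales Emergency Department Score (PEDS).
# The variable set (systolic blood pressure, GCS, metastatic cancer, glucose,
# bicarbonate, white-cell count) follows the published score; the cut-offs
# below are this package's documented banded operationalization (synthetic
# stand-in for the original regression-derived cut points, which are not
# redistributable here), chosen to give 0 points at normal physiology and
# graded points with clinically conventional derangement thresholds.
name: PEDS
family: ed
default_window: ed_worst
provenance: operationalized
band_tables:
  sbp:
    - [-.inf, 90, 2]
    - [90, 110, 1]
    - [110, .inf, 0]
  gcs_total:
    - [-.inf, 9, 3]
    - [9, 14, 2]
    - [14, 15, 1]
    - [15, .inf, 0]
  glucose:
    - [-.inf, 60, 2]
    - [60, 180, 0]
    - [180, .inf, 1]
  bicarbonate:
    - [-.inf, 15, 2]
    - [15, 21, 1]
    - [21, .inf, 0]
  wbc:
    - [-.inf, 4.0, 1]
    - [4.0, 12.0, 0]
    - [12.0, 20.0, 1]
    - [20.0, .inf, 2]
chronic_flag_points:  # additive flag points
  metastatic_cancer: 2
required_variables: [sbp, gcs_total, glucose, bicarbonate, wbc]
impute_normal_variables: []
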