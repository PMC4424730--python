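# APACHE III. Physiology, age, and chronic-health point values transcribed
# from the published tables for vital signs, oxygenation, hematology and
# chemistry. Two components are documented operationalizations rather than
# exact transcriptions (synthetic stand-ins for tables not redistributable
# here): the neurologic component, published as an eye/motor/verbal matrix,
# is mapped from the GCS total; and the acid-base component, published as a
# joint pH x pCO2 matrix, is split into marginal pH and pCO2 bands. The
# potassium bands reuse the APACHE II table. Creatinine switches to a
# two-band table under acute renal failure. Chronic-health points apply the
# single worst qualifying comorbidity and are waived for elective
# postoperative admissions.
name: APACHE3
family: icu
default_window: icu_24h_worst
provenance: transcribed  # gcs/acid-base/potassium components: operationalized
band_tables:
  heart_rate:
    - [-.inf, 40, 8]
    - [40, 50, 5]
    - [50, 100, 0]
    - [100, 110, 1]
    - [110, 120, 5]
    - [120, 140, 7]
    - [140, 155, 13]
    - [155, .inf, 17]
  map:
    - [-.inf, 40, 23]
    - [40, 60, 15]
    - [60, 70, 7]
    - [70, 80, 6]
    - [80, 100, 0]
    - [100, 120, 4]
    - [120, 130, 7]
    - [130, 140, 9]
    - [140, .inf, 10]
  temperature:
    - [-.inf, 33.0, 20]
    - [33.0, 33.5, 16]
    - [33.5, 34.0, 13]
    - [34.0, 35.0, 8]
    - [35.0, 36.0, 2]
    - [36.0, 40.0, 0]
    - [40.0, .inf, 4]
  respiratory_rate:
    - [-.inf, 6, 17]
    - [6, 12, 8]
    - [12, 14, 7]
    - [14, 25, 0]
    - [25, 35, 6]
    - [35, 40, 9]
    - [40, 50, 11]
    - [50, .inf, 18]
  pao2:  # used when FiO2 < 0.5
    - [-.inf, 50, 15]
    - [50, 70, 5]
    - [70, 80, 2]
    - [80, .inf, 0]
  aa_gradient:  # used when FiO2 >= 0.5
    - [-.inf, 100, 0]
    - [100, 250, 7]
    - [250, 350, 9]
    - [350, 500, 11]
    - [500, .inf, 14]
  hematocrit:
    - [-.inf, 41.0, 3]
    - [41.0, 50.0, 0]
    - [50.0, .inf, 3]
  wbc:
    - [-.inf, 1.0, 19]
    - [1.0, 3.0, 5]
    - [3.0, 20.0, 0]
    - [20.0, 25.0, 1]
    - [25.0, .inf, 5]
  creatinine:  # without acute renal failure
    - [-.inf, 0.5, 3]
    - [0.5, 1.5, 0]
    - [1.5, 1.95, 4]
    - [1.95, .inf, 7]
  creatinine_arf:  # with acute renal failure
    - [-.inf, 1.5, 0]
    - [1.5, .inf, 10]
  urine_output_24h:
    - [-.inf, 400, 15]
    - [400, 600, 8]
    - [600, 900, 7]
    - [900, 1500, 5]
    - [1500, 2000, 4]
    - [2000, 4000, 0]
    - [4000, .inf, 1]
  bun:
    - [-.inf, 17, 0]
    - [17, 20, 2]
    - [20, 40, 7]
    - [40, 80, 11]
    - [80, .inf, 12]
  sodium:
    - [-.inf, 120, 3]
    - [120, 135, 2]
    - [135, 155, 0]
    - [155, .inf, 4]
  potassium:
    - [-.inf, 2.5, 4]
    - [2.5, 3.0, 2]
    - [3.0, 3.5, 1]
    - [3.5, 5.5, 0]
    - [5.5, 6.0, 1]
    - [6.0, 7.0, 3]
    - [7.0, .inf, 4]
  albumin:
    - [-.inf, 2.0, 11]
    - [2.0, 2.5, 6]
    - [2.5, 4.5, 0]
    - [4.5, .inf, 4]
  bilirubin:
    - [-.inf, 2.0, 0]
    - [2.0, 3.0, 5]
    - [3.0, 5.0, 6]
    - [5.0, 8.0, 8]
    - [8.0, .inf, 16]
  glucose:
    - [-.inf, 40, 8]
    - [40, 60, 9]
    - [60, 200, 0]
    - [200, 350, 3]
    - [350, .inf, 5]
  gcs_total:  # operationalized from the published eye/motor/verbal matrix
    - [-.inf, 5, 48]
    - [5, 7, 29]
    - [7, 9, 24]
    - [9, 11, 15]
    - [11, 13, 10]
    - [13, 15, 3]
    - [15, .inf, 0]
  ph:  # operationalized from the published pH x pCO2 matrix
    - [-.inf, 7.15, 12]
    - [7.15, 7.25, 9]
    - [7.25, 7.33, 4]
    - [7.33, 7.50, 0]
    - [7.50, 7.60, 3]
    - [7.60, .inf, 12]
  pco2:
    - [-.inf, 25, 2]
    - [25, 45, 0]
    - [45, 55, 1]
    - [55, .inf, 3]
age_bands:
  - [-.inf, 45, 0]
  - [45, 60, 5]
  - [60, 65, 11]
  - [65, 70, 13]
  - [70, 75, 16]
  - [75, 85, 17]
  - [85, .inf, 24]
chronic_flag_points:  # worst single qualifying comorbidity
  aids: 23
  hepatic_failure_or_cirrhosis: 16
  metastatic_cancer: 11
  hematologic_malignancy: 10
  immunosuppressed: 10
chronic_flag_mode: max
chronic_flag_excluded_categories: [elective_postoperative]
special:
  oxygenation: apache
  oxygenation_fio2_threshold: 0.5
  creatinine_arf: switch
required_variables: [temperature, map, heart_rate, respiratory_rate, gcs_total,
                     sodium, potassium, creatinine, hematocrit, wbc, glucose,
                     bun, urine_output_24h]
impute_normal_variables: [albumin, bilirubin, ph, pco2]
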