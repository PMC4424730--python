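# APACHE II, transcribed from the published acute-physiology / age / chronic
# health point tables. Acute physiology uses the worst value in the first
# 24 ICU hours. Oxygenation: A-a gradient bands when FiO2 >= 0.5, PaO2 bands
# otherwise. Creatinine points double with acute renal failure. The GCS
# component is 15 minus the GCS total, expressed here as bands. Chronic
# health points (severe organ insufficiency or immunocompromise) depend on
# admission category: 5 for nonoperative or emergency postoperative, 2 for
# elective postoperative.
name: APACHE2
family: icu
default_window: icu_24h_worst
provenance: transcribed
band_tables:
  temperature:
    - [-.inf, 30.0, 4]
    - [30.0, 32.0, 3]
    - [32.0, 34.0, 2]
    - [34.0, 36.0, 1]
    - [36.0, 38.5, 0]
    - [38.5, 39.0, 1]
    - [39.0, 41.0, 3]
    - [41.0, .inf, 4]
  map:
    - [-.inf, 50, 4]
    - [50, 70, 2]
    - [70, 110, 0]
    - [110, 130, 2]
    - [130, 160, 3]
    - [160, .inf, 4]
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
  pao2:  # used when FiO2 < 0.5
    - [-.inf, 55, 4]
    - [55, 61, 3]
    - [61, 71, 1]
    - [71, .inf, 0]
  aa_gradient:  # used when FiO2 >= 0.5
    - [-.inf, 200, 0]
    - [200, 350, 2]
    - [350, 500, 3]
    - [500, .inf, 4]
  ph:
    - [-.inf, 7.15, 4]
    - [7.15, 7.25, 3]
    - [7.25, 7.33, 2]
    - [7.33, 7.50, 0]
    - [7.50, 7.60, 1]
    - [7.60, 7.70, 3]
    - [7.70, .inf, 4]
  sodium:
    - [-.inf, 111, 4]
    - [111, 120, 3]
    - [120, 130, 2]
    - [130, 150, 0]
    - [150, 155, 1]
    - [155, 160, 2]
    - [160, 180, 3]
    - [180, .inf, 4]
  potassium:
    - [-.inf, 2.5, 4]
    - [2.5, 3.0, 2]
    - [3.0, 3.5, 1]
    - [3.5, 5.5, 0]
    - [5.5, 6.0, 1]
    - [6.0, 7.0, 3]
    - [7.0, .inf, 4]
  creatinine:  # points double with acute renal failure
    - [-.inf, 0.6, 2]
    - [0.6, 1.5, 0]
    - [1.5, 2.0, 2]
    - [2.0, 3.5, 3]
    - [3.5, .inf, 4]
  hematocrit:
    - [-.inf, 20.0, 4]
    - [20.0, 30.0, 2]
    - [30.0, 46.0, 0]
    - [46.0, 50.0, 1]
    - [50.0, 60.0, 2]
    - [60.0, .inf, 4]
  wbc:
    - [-.inf, 1.0, 4]
    - [1.0, 3.0, 2]
    - [3.0, 15.0, 0]
    - [15.0, 20.0, 1]
    - [20.0, 40.0, 2]
    - [40.0, .inf, 4]
  gcs_total:  # 15 - GCS
    - [-.inf, 4, 12]
    - [4, 5, 11]
    - [5, 6, 10]
    - [6, 7, 9]
    - [7, 8, 8]
    - [8, 9, 7]
    - [9, 10, 6]
    - [10, 11, 5]
    - [11, 12, 4]
    - [12, 13, 3]
    - [13, 14, 2]
    - [14, 15, 1]
    - [15, .inf, 0]
age_bands:
  - [-.inf, 45, 0]
  - [45, 55, 2]
  - [55, 65, 3]
  - [65, 75, 5]
  - [75, .inf, 6]
chronic_health:
  qualifying_flags: [chronic_organ_insufficiency, immunosuppressed]
  points_by_admission_category:
    nonoperative: 5
    emergency_postoperative: 5
    elective_postoperative: 2
special:
  oxygenation: apache       # aa_gradient if fio2 >= threshold else pao2
  oxygenation_fio2_threshold: 0.5
  creatinine_arf: double
mortality_transform:        # logit(p) = intercept + slope*score (+ emergency surgery term)
  intercept: -3.517
  slope: 0.146
  emergency_surgery: 0.603
required_variables: [temperature, map, heart_rate, respiratory_rate, gcs_total,
                     sodium, potassium, creatinine, hematocrit, wbc]
impute_normal_variables: [ph]
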