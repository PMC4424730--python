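# Physiology variable registry: units, plausibility bounds, normal reference
# values (used for missing-as-normal imputation and worst-value tie-breaking),
# and the generative parameters used by the synthetic cohort simulator.
#
#   normal      : reference value imputed when the missing-as-normal policy applies
#   lo, hi      : plausibility bounds; out-of-range values are rejected at ingest
#   effect      : derangement per unit of latent severity, in the variable's units
#   p_high      : probability a deranged patient excurses toward the high tail
#                 (1.0 = always high, 0.0 = always low)
#   noise_sd    : within-patient measurement noise (same units)
#   integer     : values are reported as integers
variables:
  temperature:      {units: degC,     normal: 37.0, lo: 25.0,  hi: 46.0,   effect: 1.6,  p_high: 0.6,  noise_sd: 0.4}
  heart_rate:       {units: bpm,      normal: 75,   lo: 0.0,   hi: 300.0,  effect: 28.0, p_high: 0.85, noise_sd: 9.0, integer: true}
  respiratory_rate: {units: bpm,      normal: 14,   lo: 0.0,   hi: 80.0,   effect: 8.0,  p_high: 0.9,  noise_sd: 2.5, integer: true}
  sbp:              {units: mmHg,     normal: 120,  lo: 20.0,  hi: 300.0,  effect: 30.0, p_high: 0.15, noise_sd: 10.0, integer: true}
  map:              {units: mmHg,     normal: 85,   lo: 20.0,  hi: 250.0,  effect: 22.0, p_high: 0.15, noise_sd: 8.0, integer: true}
  spo2:             {units: percent,  normal: 98,   lo: 30.0,  hi: 100.0,  effect: 7.0,  p_high: 0.0,  noise_sd: 1.5, integer: true}
  gcs_total:        {units: points,   normal: 15,   lo: 3.0,   hi: 15.0,   effect: 3.5,  p_high: 0.0,  noise_sd: 0.8, integer: true}
  fio2:             {units: fraction, normal: 0.21, lo: 0.21,  hi: 1.0,    effect: 0.22, p_high: 1.0,  noise_sd: 0.03}
  pao2:             {units: mmHg,     normal: 95,   lo: 20.0,  hi: 700.0,  effect: 22.0, p_high: 0.0,  noise_sd: 8.0}
  aa_gradient:      {units: mmHg,     normal: 10,   lo: 0.0,   hi: 700.0,  effect: 90.0, p_high: 1.0,  noise_sd: 15.0}
  ph:               {units: unitless, normal: 7.40, lo: 6.5,   hi: 8.0,    effect: 0.09, p_high: 0.2,  noise_sd: 0.02}
  pco2:             {units: mmHg,     normal: 40,   lo: 5.0,   hi: 200.0,  effect: 11.0, p_high: 0.5,  noise_sd: 3.0}
  sodium:           {units: mmol/L,   normal: 140,  lo: 90.0,  hi: 200.0,  effect: 7.0,  p_high: 0.5,  noise_sd: 2.0, integer: true}
  potassium:        {units: mmol/L,   normal: 4.0,  lo: 1.0,   hi: 10.0,   effect: 0.8,  p_high: 0.6,  noise_sd: 0.2}
  creatinine:       {units: mg/dL,    normal: 0.9,  lo: 0.1,   hi: 25.0,   effect: 1.4,  p_high: 1.0,  noise_sd: 0.15}
  bun:              {units: mg/dL,    normal: 14,   lo: 1.0,   hi: 250.0,  effect: 22.0, p_high: 1.0,  noise_sd: 3.0, integer: true}
  bicarbonate:      {units: mmol/L,   normal: 24,   lo: 2.0,   hi: 60.0,   effect: 5.5,  p_high: 0.1,  noise_sd: 1.2, integer: true}
  glucose:          {units: mg/dL,    normal: 100,  lo: 10.0,  hi: 1500.0, effect: 90.0, p_high: 0.9,  noise_sd: 15.0, integer: true}
  bilirubin:        {units: mg/dL,    normal: 0.8,  lo: 0.05,  hi: 60.0,   effect: 2.2,  p_high: 1.0,  noise_sd: 0.2}
  albumin:          {units: g/dL,     normal: 4.0,  lo: 0.5,   hi: 7.0,    effect: 0.9,  p_high: 0.0,  noise_sd: 0.2}
  hematocrit:       {units: percent,  normal: 42,   lo: 5.0,   hi: 75.0,   effect: 7.5,  p_high: 0.2,  noise_sd: 1.5}
  wbc:              {units: 1e9/L,    normal: 8,    lo: 0.01,  hi: 200.0,  effect: 7.0,  p_high: 0.85, noise_sd: 1.2}
  urine_output_24h: {units: mL,       normal: 2400, lo: 0.0,   hi: 20000.0, effect: 700.0, p_high: 0.0, noise_sd: 200.0, integer: true}
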