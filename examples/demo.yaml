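seed: 7
simulate:
  n_patients: 3
  days_per_patient: 2
har:
  duration_s: 5.0
  stride_s: 5.0
  classifier: baseline_features
  subjects_per_source: 4
  train_minutes_per_subject: 10
gesture:
  sd_threshold_g: 0.01
  window_s: 1.0
  max_gap_s: 1.0
features:
  min_wear_h: 8.0
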