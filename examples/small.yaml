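# Small synthetic cohort for a quick end-to-end run.
scenario:
  n_patients: 6
  days_per_patient: 50
  n_true_profiles: 2
  pattern_segments:
    - [0, [0.15, 0.85]]
    - [25, [0.85, 0.15]]
  event_lag_days: 3
  p_event_given_change: 0.5
profiling_k_max: 3
profiling_restarts: 2
bocpd:
  hazard: 0.0333
  n_profile_samples: 0
stability_threshold: 0.5
eval_n_thresholds: 20
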