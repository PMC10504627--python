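# phenorisk

Passive smartphone-monitoring analysis pipeline: turn per-patient raw
sensor streams (GPS fixes, step counts, app-usage events) into daily
behavioral profiles, detect behavioral change points online, raise
1-week risk alarms, and evaluate them at the day level with ROC/AUC.
A synthetic cohort generator with planted ground truth (profiles,
change points, risk events, missingness) makes the whole pipeline
testable without any external data.

## Pipeline stages

1. **synthetic** (`phenorisk.synthetic`) — renders seeded raw sensor
   streams per patient from a piecewise-constant latent-profile
   scenario, couples risk events to planted change points, and injects
   partial/total missingness.
2. **preprocess** (`phenorisk.preprocess`) — bins each day into four
   48-dimensional half-hourly vectors: log1p distance traveled
   (differenced GPS traces), binary at-home (night-dwell home
   inference, 200 m radius), log1p steps, binary app usage; with
   per-bin observed/missing masks.
3. **profiling** (`phenorisk.profiling`) — per-patient heterogeneous
   mixture model (diagonal Gaussian x Bernoulli components, up to 10
   profiles) fitted by EM with exact marginalization of missing
   dimensions; the number of profiles is selected by BIC; emits per-day
   profile posteriors.
4. **changepoint** (`phenorisk.changepoint`) — Bayesian online
   change-point detection over the profile sequence: run-length
   ("days since last change") posterior under a constant hazard with
   Dirichlet-categorical predictive, profile uncertainty handled by
   sampling posterior label paths, totally missing days marginalized
   exactly.
5. **detection** (`phenorisk.detection`) — alarms where the cumulative
   probability of a change within the previous 7 days exceeds a
   stability threshold.
6. **evaluation** (`phenorisk.evaluation`) — day-level TP/FP/FN/TN
   against risk events (forward 7-day prediction window, monitoring
   truncated at the first event), pooled ROC over 50 thresholds in
   (0,1), trapezoidal AUC, and cohort event summaries.

## CLI

```bash
# end-to-end on a synthetic cohort
phenorisk run-all --config examples/small.yaml --seed 7 --out-dir run/

# or stage by stage
phenorisk simulate   --config examples/small.yaml --seed 7 --out-dir run/
phenorisk preprocess --streams run/streams.jsonl --out run/features.csv
phenorisk profile    --features run/features.csv --out run/posteriors.csv
phenorisk changepoint --posteriors run/posteriors.csv --out run/change_prob.csv
phenorisk detect     --series run/change_prob.csv --threshold 0.5 --out run/alarms.csv
phenorisk evaluate   --series run/change_prob.csv --events run/events.csv --out run/roc.csv
```

All artifacts are plain text (JSONL/CSV/JSON); every stage is
deterministic given its seed (`n_profile_samples=0` selects the fully
deterministic expected-profile mode of the change-point filter).

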