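# gaitpredict

Short-horizon (≈1 s) prediction of a walking person's position from a
waist-level landmark track, using discrete kinematic motion models
(CV, CA, CTRV, CTRA) whose inputs are corrected for gait biomechanics.

Position-derived speed and heading oscillate with the step cycle, which
wrecks recursive dead-reckoning. The package provides three estimation
routes for the model inputs:

- **raw** — backward differences of the sampled positions, oscillation and
  all;
- **offline** — states derived from a whole-signal polynomial-regression
  baseline (acausal reference, degree 1 for straight walks, degree 8 for
  single-turn curves);
- **realtime** — causal compensation: the speed is held at foot-contact
  events (detected as extrema of the speed derivative), the acceleration is
  the speed increment between events, and the heading is a per-subject
  calibrated blend `K·pelvis_yaw + (1−K)·raw_heading` that cancels the
  counter-phase sway oscillation.

A synthetic gait generator (`gait_synthesizer`) produces structured walks
with ground truth (smooth baseline, contact times, blend gain) and a seeded
benchmark of 5 subjects × (5 straight + 5 curved) walks, standing in for
motion-capture recordings that are not publicly available.

## CLI

All positions are metres, angles radians, indices 0-based with half-open
intervals. Trajectory CSVs have the header `t_s,x_m,y_m,pelvis_yaw_rad`.

```sh
# generate a synthetic walk (straight or circle)
gaitpred simulate --path circle --radius 1.5 --speed 1.0 --stride-hz 1.0 \
    --seed 7 --out walk.csv --truth-out truth.csv

# raw state estimation (with the 3rd-order 6 Hz Butterworth prefilter)
gaitpred estimate walk.csv --out states.csv

# offline polynomial baseline (degree 8 for a single-turn curve)
gaitpred baseline walk.csv --degree 8 --out smooth.csv

# per-subject blend-gain calibration against the baseline
gaitpred calibrate walk.csv --degree 8

# recursive prediction from one start sample
gaitpred predict walk.csv --model ctrv --variant realtime --start 200 \
    --horizon-s 1.0 --out pred.csv

# full horizon-error sweep: RMS at 1 s per model and variant
gaitpred evaluate walk.csv --models cv,ca,ctrv,ctra \
    --variants raw,offline,realtime --horizon-s 1.0 --out table.csv

# the whole benchmark pipeline (simulate -> estimate -> calibrate -> evaluate)
gaitpred run --seed 1 --out-dir results/
```

`gaitpred run` accepts a YAML config (see `gaitpredict.cli._DEFAULT_CONFIG`
for the schema and defaults: 100 Hz sampling, 6 Hz prefilter, 1 s horizon,
automatic K calibration). It writes `summary.csv` (columns
`model,variant,path_type,horizon_s,rms_mm,n_starts`) and `run_log.json`
(config hash, seed, version, per-subject K).

## Layout

| module | contents |
| --- | --- |
| `motion_models` | `MotionState`, the four models, exact one-step/multi-step propagation |
| `state_estimation` | `Trajectory`, CSV I/O, Butterworth prefilter, raw state estimation |
| `offline_baseline` | polynomial baseline fit and offline states |
| `gait_compensation` | contact detection, velocity hold, orientation blend, K calibration |
| `horizon_prediction` | recursive prediction, error sequences, RMS sweeps, summary table |
| `gait_synthesizer` | synthetic walks with ground truth, seeded benchmark suite |
| `cli` | click CLI, YAML config validation, pipeline runner |
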