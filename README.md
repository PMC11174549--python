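# gyrogait

Real-time step detection and per-step distance estimation from a
shank-mounted gyroscope, together with a synthetic test-circuit simulator
and the agreement-statistics suite used to validate such algorithms.

The detector is a causal toe-off → mid-swing → initial-contact state
machine over the sagittal-plane (pitch) angular velocity of the shank:

* samples are low-pass filtered (2nd-order Butterworth, 5 Hz cut-off,
  causal by default, zero-phase available offline);
* toe-off (TO) and initial contact (IC) are extrema whose magnitude must
  reach 1 rad/s; mid-swing (MSW) is the opposite-sign extremum in between;
* the flight time `t_IC − t_TO` must fall within a configurable window
  (80 ms – 1.5 s) and a 250 ms refractory follows every detected step;
* angular displacement is integrated (`ω·Δt`) from TO, accumulated
  separately for positive and negative increments; the larger magnitude
  wins sign-preserved, which is how backward steps are recognized, and the
  searched peak polarity adapts when the walking direction flips;
* per-step distance is the chord model `d = L·√(2(1−cos θ)) = 2L·sin(|θ|/2)`
  with the athlete's configured leg length `L`, clamped at `|θ| = π`;
* integrators reset after every step so integration drift never propagates.

Because the validation study's raw dataset is not shareable, the `synth`
module generates labelled sessions with exact ground truth: per-pace
raised-cosine gait cycles (walking, jogging, sprinting, run with changes
of direction, ball dribbling, backward), the six-segment 201.6 m test
circuit, three vertical-jump sync spikes, additive sensor noise, constant
bias, and two-device variants with gain/noise/offset deltas.

The `agreement` module implements the validation statistics: MAE/RMSE/MAPE,
Lin's concordance correlation coefficient, repeated-measures Bland-Altman
limits of agreement (random-intercept model on paired differences), the
total deviation index, the coefficient of individual agreement,
REML variance-component fits of the paired step-count model with AIC/BIC
model ranking, and inter-unit reliability summaries (mean difference, LoA,
coefficient of variation). Confidence intervals use a seeded cluster
bootstrap over subjects.

## CLI

```sh
# generate a synthetic session (gyro CSV + ground truth + segment labels)
gyrogait simulate --circuit default --laps 5 --seed 42 --out session/

# detect steps in a gyro CSV (columns t,gyro_pitch[,gx,gy,gz])
gyrogait detect --input session/device1_gyro.csv --leg-length 0.92 \
    --out steps.csv

# agreement report between two per-lap tables
# (columns subject,activity,lap,value)
gyrogait agree --estimated est.csv --reference ref.csv --out report.json
```

All commands take `--log-level`; `detect` accepts `--config cfg.json`
(strict-keyed detector thresholds), `--time-unit ms`, `--no-filter` and
`--zero-phase`.

## Layout

| module | contents |
| --- | --- |
| `gyrogait.core` | domain types, gyro/steps CSV I/O, JSON configs, default circuit |
| `gyrogait.preprocess` | Butterworth low-pass, magnitude spectrum, jump-spike synchronization |
| `gyrogait.detector` | the TO→MSW→IC state machine (streaming and batch) |
| `gyrogait.distance` | displacement selection, chord distance, integrator reset |
| `gyrogait.synth` | pace profiles, session generator, two-device variants |
| `gyrogait.agreement` | error metrics, CCC, LoA, TDI, CIA, LMM variance components, inter-unit reliability |
| `gyrogait.benchmarks` | published validation figures used as fixtures and simulation truths |
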