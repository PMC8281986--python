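# reachkin

Kinematic analysis of reaching movements recorded by a low-cost wrist-worn
3-axis accelerometer, built around a Go/No-Go motor-inhibition paradigm.

In the task, a frequent cue (75% of trials) primes a *dominant* reach and a
rare cue (25%) demands inhibiting it and selecting a *non-dominant*
alternative. Each trial carries four timestamps — P (hand pressed on the
start sensor), S (stimulus onset, after a uniform 0–2,000 ms foreperiod),
R (hand release), A (answer touch) — defining reaction time RT = R−S,
movement duration MD = A−R, and the foreperiod S−P (*StimulusRandomTime*).

The core kinematic endpoint is the **time-to-peak-velocity percentage**

> TPV% = 100 · (t_peak − R) / (A − R),

an asymmetry index of the speed profile: minimum-jerk reaches peak at 50%,
and a larger TPV% indicates a movement weighted toward planning rather than
online correction. Because a wrist accelerometer has no gyroscope, velocity
must be reconstructed by cumulative trapezoidal integration of the
gravity-corrected acceleration, and any residual sensor bias integrates into
a velocity ramp that can bury the bell-shaped speed profile under a monotone
curve with a false peak at the end of the movement. The pipeline removes
that ramp by subtracting the least-squares line from the speed magnitude
(linear detrending) before locating the peak, and applies an a-priori
inclusion band of [5%, 95%] to the resulting TPV values. Only the *timing*
of the peak is treated as trustworthy; velocity magnitudes are flagged as
diagnostics, never endpoints.

Inference on TPV (rescaled to (0, 1)) uses beta mixed-effects regression
with a logit link and a participant random intercept,

> TPV ~ Beta(μφ, (1−μ)φ), logit(μ) = Xβ + b, b ~ N(0, σ_b²),

fitted by adaptive Gauss–Hermite quadrature, over the nested ladder
mb0 (intercept), mb1 (+condition), mb2 (+StimulusRandomTime),
mb3 (condition × StimulusRandomTime), compared with AICc Akaike weights and
likelihood-ratio tests.

Because no public recordings exist for this paradigm, the package ships a
first-class simulator: analytic minimum-jerk and asymmetric reach profiles
with exactly controllable TPV, a MEMS sensor model (±8 g, 12-bit, 100 Hz,
bias/noise/quantization/clipping), and a full session generator (160 valid
trials per session under a 180-trial cap, with anticipations, omissions and
incorrect responses). Every processing stage is validated against this
ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study; computation
lives in the library (`reachkin.*`), the scripts only orchestrate and
report:

```bash
python analysis/01_simulate_study.py --seed 1   # 19 raw sessions -> scratch/
python analysis/02_extract_kinematics.py        # calibrate, integrate, TPV%
python analysis/03_fit_models.py                # beta-GLMM ladder comparison
```

which prints (seed 1):

```
processed 19 sessions, 3171 trials
  2982 correct, 58 incorrect, 111 omissions, 20 anticipations
  TPV exclusions (outside 5-95%): 0
      dominant: RT 561 ms, MD 497 ms, TPV 40.9% (n=2215)
  non-dominant: RT 594 ms, MD 581 ms, TPV 44.7% (n=767)

model  df   loglik      aicc  aicc_weight   chi2     p
  mb0   3 1990.321 -3974.633        0.000    NaN   NaN
  mb1   4 2019.281 -4030.549        0.644 57.922 0.000
  mb2   5 2019.330 -4028.639        0.248  0.096 0.756
  mb3   6 2019.500 -4026.971        0.108  0.341 0.559
best model by Akaike weight: mb1 (weight 0.64)
```

Reading this: the inhibition condition slows both planning (RT +33 ms) and
execution (MD +84 ms) and shifts the velocity peak later (TPV 40.9% → 44.7%),
recovered by the full sensor → integration → detrend chain from raw
simulated accelerometry. The model comparison picks mb1 — the generator's
default encodes a condition effect of logit(0.45) − logit(0.40) and no
foreperiod effect, and the ladder's χ² (57.9 on 1 df) quantifies exactly
that effect. Small tables land in `results/`; bulky per-sample traces stay
in `scratch/`.

The same machinery is exposed as a CLI (`reachkin simulate | preprocess |
kinematics | fit | report | run-all`) for use on externally recorded
trace/event CSV files.

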