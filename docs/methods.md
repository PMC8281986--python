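# Methods

This note documents the models, conventions and numerical choices behind
`reachkin`, and what the synthetic-data studies do and do not demonstrate.

## Reach profiles

Two analytic families provide ground truth (`reachkin.profiles`).

**Minimum-jerk reach.** Position x(τ) = A(10τ³ − 15τ⁴ + 6τ⁵), τ = t/T, with
velocity and acceleration as exact derivatives. The speed profile is the
symmetric bell with peak 1.875·A/T at τ = 1/2; rest-to-rest boundary
conditions hold exactly.

**Asymmetric reach.** No standard parametric family exists for reaches with
a prescribed time-to-peak-velocity fraction m, so we use a beta-shaped speed
bump s(τ) ∝ τ^a(1−τ)^b with a = c·m, b = c·(1−m): its mode is a/(a+b) = m
*exactly* for any concentration c, which makes recovery tests sharp. The
default c = 6 gives bumps of minimum-jerk-like width (the minimum-jerk speed
is itself the c = 4, m = ½ member); c is raised automatically so that
min(a, b) > 1, keeping endpoint acceleration finite and zero. Position is
the regularized incomplete beta function and the speed integral equals the
amplitude in closed form.

## Sensor model

The simulated MEMS accelerometer (±8 g, 12 bits, 100 Hz — one LSB =
16 g/4096 = 3.90625 mg) reports, in g: R·(a_body/g₀ + ĝ) + bias + noise,
clipped to ±range and rounded to the ADC grid. Conventions: g₀ =
9.80665 m/s²; gravity lies along sensor +z at identity orientation (the
resting hand sits flat on the start sensor); orientation is fixed within a
trial. The device has no gyroscope, so true orientation during the reach is
unobservable — this is precisely why the downstream analysis only trusts
peak *timing*. An optional slow orientation drift (rad/s about a chosen
axis) is provided as a stress input; it is off by default because the
emulated task re-anchors posture at every trial.

## Session generator

Defaults encode the emulated study conditions: 160 valid trials required,
180-trial cap, 75/25 dominant/non-dominant cue mix, uniform 0–2,000 ms
foreperiod, 2,000 ms response window. Per-condition RT/MD are lognormal
(strictly positive, right-skewed) with moments matched to the study's
descriptives (dominant 558±136 / 500±167 ms; non-dominant 601±163 /
591±207 ms). Since validity requires the answer inside the response window,
(RT, MD) pairs are rejection-sampled until RT + MD ≤ 2,000 ms; this joint
truncation shifts generated means by only a few ms (covered by test
tolerances). Invalid-trial rates (anticipation 0.7%, omission 3.4%,
incorrect 1.8%) are the observed frequencies of the emulated study's
3,145-trial pool. Anticipations release during the foreperiod and receive
no stimulus (S and A absent); omissions have no release or answer.
Incorrect responses share the kinematics of correct ones and differ only in
the log, so downstream filters are exercised. The foreperiod distribution
is assumed uniform over its range (only the range is known).

Each valid trial's true TPV fraction is drawn from the logit-link beta
model below; the corresponding asymmetric reach (default amplitude 0.35 m,
an arm-length touch) is written into the body-acceleration timeline at
[R, A], followed by a return movement, so the whole continuous trace is
physically coherent. A single integer seed fans out to per-component
substreams (conditions, foreperiods, validity, RT/MD, TPV, sensor noise)
via `numpy.random.SeedSequence.spawn`; identical seed + parameters gives
byte-identical output.

## Calibration and gravity removal

The in-situ calibration stage estimates per-axis offsets from rest windows
(≥ 0.5 s with the hand on the start sensor, plus the pre-session rest). The
default "reference" mode assumes the resting posture puts gravity along a
configured sensor axis (+z), so bias = rest-mean − ĝ; this identifies all
three bias components. A "radial" mode (bias = mean − mean/|mean|) makes no
directional assumption but is blind to bias orthogonal to gravity; both are
exposed in configuration because the original acquisition protocol's exact
calibration is not specified. A scalar scale maps the corrected rest
magnitude to exactly 1 g. Gravity removal subtracts the per-trial
rest-window ([P, S]) mean vector and converts to m/s²; windows shorter than
0.2 s or failing a stillness check (per-axis SD > 0.05 g) fall back to the
session-level gravity estimate and flag the trial. An optional zero-phase
low-pass filter exists but is off by default — the emulated analysis did
not filter before integration.

## TPV extraction

Per valid trial: (1) snap [R, A] to the nearest trace samples (event and
sensor clocks are asynchronous); (2) cumulative trapezoidal integration per
axis with C = 0 at R — the task guarantees the hand rests on the sensor
until release; (3) Euclidean speed magnitude; (4) subtraction of the
whole-window least-squares line from the magnitude (magnitude only, not
components; whole-window linear rather than piecewise, with the alternative
reachable by disabling the stage); (5) the global maximum, earliest sample
on ties, gives TPV% = 100·(t_peak − R)/(A − R); flat series are excluded as
having no defined peak. Window endpoints participate in the peak search;
the [5, 95]% inclusion band (closed at both ends, fixed for determinism)
handles boundary pathologies. TPV% is invariant to positive rescaling of
the window's acceleration — a designed property, since integration and
detrending distort velocity *values*.

Why detrending matters: a constant residual bias b integrates to a ramp
|b|·t that can exceed the true speed bump, making the magnitude a monotone
increasing curve with a false maximum at the window end. The regime where
this bites hardest is long, low-amplitude movements: for a 1.5 s, 0.10 m
reach, ~10 mg of bias on the axes orthogonal to motion moves the raw peak
to the window end, while the detrended peak stays within 3 percentage
points of truth. For fast large reaches the bias is negligible either way.
Note the detrend line itself tilts an asymmetric bump, shifting the peak by
1–2 points even without bias; this inherent cost is included in the 3-point
drift-robustness contract.

## Beta mixed model

TPV/100 ∈ (0, 1) is modelled as Beta(μφ, (1−μ)φ) — the mean–precision
parameterization, Var = μ(1−μ)/(1+φ) — with logit(μ) = Xβ + b and a
participant random intercept b ~ N(0, σ_b²). The fixed-effect ladder
mb0/mb1/mb2/mb3 (intercept; +condition; +foreperiod; interaction) uses
dominant as the reference level, and the reported parameter count
k = #β + 2 gives 3, 4, 5, 6. The foreperiod is z-scored inside the
optimizer (ms-scale predictors ill-condition the Hessian); centering
constants are stored on the fit for back-transformation.

The marginal likelihood integrates b out per participant with *adaptive*
Gauss–Hermite quadrature, default order 15: a damped, safeguarded Newton
iteration (analytic first and second derivatives, tolerance 1e-11) finds
each participant's conditional mode and curvature, and the Hermite rule is
centred and scaled there. On toy tables this matches brute-force dense-grid
integration to ~1e-12, comfortably inside the 1e-6 oracle tolerance used in
tests; σ_b < 1e-8 degenerates exactly to plain beta regression.
Optimization is L-BFGS-B on (β, log σ_b, log φ) with bounds
σ_b ∈ [1e-3, 3], φ ∈ [0.5, 5·10⁴], from a moment-matched start (logit-scale
OLS for β, between-participant spread for σ_b, beta-variance inversion for
φ) plus a near-zero-σ_b second start; conditional modes are cached between
objective evaluations as warm starts. Wald standard errors come from the
numerical Hessian at the optimum. AICc uses the standard
−2ℓ + 2k + 2k(k+1)/(n−k−1) correction; Akaike weights are
exp(−Δ/2)/Σexp(−Δ/2); adjacent-model LRTs report χ² = 2Δℓ (clipped at 0
against numerical jitter), Δdf = Δk and the chi-square upper tail,
unadjusted for multiplicity. Both LRT and Wald p-values are reported, since
they answer slightly different questions for the selected model.

An independent cross-check in the test suite fits the same model with R's
glmmTMB (Laplace approximation) and agrees with the quadrature fit to
~1e-3 in coefficients on a 400-trial table.

## Generating defaults for the inference stage

The beta-GLMM generator defaults put the dominant-condition mean at 40%
and the non-dominant at 45% (condition effect logit(0.45) − logit(0.40) ≈
0.205 on the link scale), σ_b = 0.2 and φ = 12, which together reproduce
the emulated study's ~15–17% TPV standard deviations. The default
foreperiod effect is zero: the emulated analysis found that effect
statistically non-significant, so the simulator encodes only the supported
effect. Consequently, on simulated data the model comparison correctly
concentrates weight on mb1 rather than mb2 — the analysis scripts
demonstrate the machinery, not a re-derivation of the original dataset's
weights, which would require the unreleased recordings.

## Problem sizes used by the simulation studies

Confidence-interval coverage uses 100 studies of 19 participants × 150
trials (the emulated study's scale). The LRT type-I study uses 500 seeds of
10 × 30 (the null-calibration property is size-free, and this keeps the
study quick); model-selection consistency uses 100 seeds at 19 × 150 with
quadrature order 7, and the simulation loops generally use orders 7–9 —
adaptive quadrature is already grid-converged there, as the order-15
default's agreement with the dense-grid oracle shows.

## What the synthetic studies do not show

The simulator emulates sensor physics (bias, noise, quantization,
saturation) and task structure, but not: extra-task movements (the source
of most real TPV exclusions — simulated sessions at default noise produce
essentially none), orientation change *during* a reach (wrist rotation),
sensor-clock drift relative to the task software, or non-beta-shaped true
speed profiles (double peaks from corrective submovements). Passing the
recovery suites therefore validates the numerics and the inferential
machinery, not the behavioural claims of any particular dataset.

## Known limitations

* The reference-direction calibration assumes a consistent resting posture;
  a tilted rest posture biases the gravity estimate (the radial mode is the
  conservative alternative).
* Whole-window linear detrending only cancels drift that is approximately
  linear over [R, A]; strongly time-varying bias (temperature transients,
  rapid orientation change) is out of contract.
* The beta GLMM uses random intercepts only, matching the candidate set it
  implements; random slopes are deliberately out of scope.
* Velocity-value indices (mean/peak speed) are computed internally but
  never reported as endpoints; after integration and detrending they are
  not metrically meaningful.
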