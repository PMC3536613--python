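# Methods

This note documents the models, estimators and numerical choices behind
`ictrack`, in the order the pipeline runs them.

## Virtual controlled systems (`ictrack.plants`)

One-dimensional linear loads driven by a joystick-like input `u`:

* order 0: `y = G·u` (pure feedthrough),
* order 1: `ẏ = G·u`,
* order 2 marginally stable: `ÿ = G·u` (a pure mass),
* order 2 unstable: `ÿ = y/τ² + G·u`, one real pole at `+1/τ`; the default
  τ = 0.92 s matches the divergence time constant of quiet standing.

The input gain defaults to `G = 1` screen unit; only the delay structure,
not the gain, enters the analysis, so gains are configurable but
uncalibrated.  State = position (and velocity); output = position; time in
seconds everywhere, milliseconds only in rendered reports.  Systems are
discretized by exact zero-order hold (`scipy.signal.cont2discrete`) at the
1 kHz simulation rate.  A reset rule (state zeroed when |y| exceeds the
display limit, instant logged) emulates the return-to-centre intervention
when the dot leaves the screen; it is disabled by default so reference
trajectories stay analytic.

## Stimuli (`ictrack.stimulus`)

Targets are piecewise constant.  Four patterns (left negative): reversals
`0 → ±A → 0` and unidirectional triples `0 → ±A → ±2A → 0`, the third
(return) step placed one approximate recovery period (ARP) after the
second.  The reversal is taken to return to the previous level rather than
overshoot; amplitudes are in arbitrary screen units with `A = 1` default.
Eight ISIs per system order (0: 0.05–1.0 s, 1st: 0.10–2.5 s, 2nd:
0.15–4.0 s) and ARPs drawn uniformly from 1–2 s, 2–3 s and 4–5 s
respectively.  A session presents each ISI × pattern combination a fixed
number of times in seeded random order; ISI counts per session are exactly
uniform, and reversal/unidirectional trials equinumerous.  Step instants
are aligned to the 1 ms grid by rounding.

## Controllers (`ictrack.controller`)

Both controllers are built on delay compensation: the feedback gain `k` is
a continuous-time LQR design (unit weights; any stabilizing design
satisfies the same contracts), a Luenberger observer with fast
(near-deadbeat at 1 kHz) poles estimates the state from the measured
output, and a model-based predictor rolls the delayed estimate forward
over the pure feedback delay `t_d`, removing the delay from the loop
dynamics.  The neuromuscular block defaults to identity (a first-order lag
is available through `nms_time_constant`), which keeps response-onset
timing analytically checkable.

**Continuous control** applies `u = u_ff(w) − k(x̂_pred − x_ref(w))` every
sample, on target information that is `t_d` old: an isolated step is
answered exactly `t_d` later.

**Intermittent control** feeds the predicted state to a *system-matched
hold*: the hold state evolves under the delay-free closed-loop dynamics
`x_h ← (A − Bk)x_h` and the control is `u = u_ff(w_h) − k·x_h`.  In the
matched, noise-free case the hold exactly replays what continuous control
would do, so the two coincide whenever an event accompanies every target
change — intermittency only becomes visible when the open-loop interval
defers an event.  Events obey the three trigger conditions (single
detection within `Δs`; at least `Δ_OL` since the last event; error above
threshold, strictly nonzero when the threshold is zero).

Trigger modes:

* **external** — one event per target step, deferred to respect `Δ_OL`
  and absorbed if inside a previous event's sampling window.  Noise-free
  timing law (the oracle for all slope checks):
  onset = max(step, previous event + Δ_OL) + Δs + t_d.
* **internal** — events fired at run time when the prediction-error signal
  exceeds the threshold.  With threshold zero and a persistent error the
  train saturates at rate 1/Δ_OL.  The *saturated regime* can be pinned
  explicitly via `free_run_phase`: events at `phase + k·Δ_OL` regardless
  of error, the limit a zero threshold reaches under noise.  This is the
  configuration used for the slope −1/2 condition; the exact noise path to
  saturation is exposed as parameters (threshold, noise SD, phase) because
  only the limiting behaviour is well defined.

With a **sampling delay** `Δs > 0`, a step falling inside the window
between an event and its sample is absorbed: the sample then reflects both
steps and the response goes straight to the final level.  For
unidirectional pairs this combined response is observable and the
reconstructed RT2 falls again for ISI < Δs, producing a peak in mean RT2
at ISI ≈ Δs; for reversals the absorbed pair leaves no movement at all
(the target is back at centre when sampled), so those trials are screened
out rather than assigned arbitrary delays.  The optional first-order
low-pass filter on the set point is off by default.

## Stage 1 — set-point reconstruction (`ictrack.reconstruction`)

The closed-loop target→control relationship is modelled as a low-order,
zero dead-time LTI map; response delays are the step-instant shifts that
optimize the fit.  Two stages: the *time-invariant* stage shifts all steps
equally (the response's common delay); the *non-time-invariant* stage then
adjusts each step individually, sequentially in temporal order and in
repeated passes (default max 6) until the residual stops improving.  Ties
resolve to the smallest delay.  Per-trial flags record non-convergence and
merged (coincident) reconstructed instants; trials whose control signal
never moves (relative SD below 10⁻⁶ of the step amplitude) are screened
out and logged, since no delay is identifiable.

Numerical choices:

* **Identification rate 100 Hz** (`dt_id` = 0.01 s).  All experiment ISIs,
  the reference delays and the 1 ms simulation grid are commensurate with
  10 ms, so every step instant is representable exactly on the
  identification grid; a 10th-order rational model can still span slow
  dynamics through its poles.  The delay grid spans 0–1.5 s in 10 ms
  steps; negative delays are disallowed (responses cannot precede stimuli
  in this design).
* **Block-average decimation.**  Both the recorded response and every
  candidate reconstructed target are decimated by averaging 10-sample
  blocks.  Block averaging commutes with shifts that are multiples of the
  identification step — so noise-free delay recovery is exact — and
  attenuates white measurement noise tenfold in power.  A generic
  zero-phase FIR decimator would smear step transitions acausally and bias
  a causal zero-delay fit toward earlier instants.
* **All-pole scoring model.**  Candidate configurations are scored by the
  residual of `u[t] = Σᵢ aᵢ·u[t−i] + b₀·w[t] + c` (AR order 10, direct
  feedthrough, intercept).  A model with a free numerator of span *n* lags
  owns *n* grid steps of dead-time capacity, which makes per-step delays
  unidentifiable (a flat residual plateau on pure-delay responses);
  forcing the single feedthrough term pins all latency into the explicit
  step shifts.  The general rational fit (full numerator) remains
  available in `fit_lti_map` for diagnostics, and `aic_by_order` logs AIC
  over orders 1–12 so the default order can be checked against the
  information-criterion optimum.
* The fixed (response-lag) Gram blocks are precomputed per trial, so one
  candidate evaluation costs a small linear solve; minimum-norm solutions
  handle collinear targets gracefully.

Only the first two steps of a trial form the (RT1, RT2) pair; the
return-to-centre step of unidirectional trials is reconstructed (it is
part of the target) but excluded from the pair.

## Stage 2 — statistics (`ictrack.stats`)

Repetitions are averaged within participant before testing; participants
are the random factor throughout.  The six-test battery:

1. 5–95% percentile ranges of RT1 vs RT2 (linear-interpolation
   convention), compared across participants;
2. Step Number main effect (RT2 > RT1?);
3. Step Number × ISI interaction;
4. RT1 vs ISI (a refractory process leaves RT1 independent of ISI);
5. per-ISI two-tailed paired t-tests: the **ANOVA metric** is the largest
   ISI such that it and every smaller ISI shows RT2 significantly above
   RT1 (α = 0.05, uncorrected by default, Holm optional); a
   midpoint-interpolated variant is reported alongside, and a flag marks
   the metric as unbounded when every ISI is significant;
6. ordinary least squares of mean RT2 on ISI over the interfered ISIs
   (those flagged in 5): the **maximum increase in RT2** is the intercept
   at ISI = 0 minus mean RT1.  The slope −1 constrained fit has intercept
   `mean(RT2 + ISI)`; its intercept minus mean RT1 is the single-channel
   estimate of the refractory duration.

The repeated-measures ANOVA is computed from contrast-projected scores
(fully within-subject; error term = effect × subject), which reproduces
the classical sums-of-squares F exactly and yields per-effect sphericity
estimates from the projected covariance.  Every effect with more than two
levels uses ε = min(1, (ε_GG + ε_HF)/2) on both degrees of freedom.
Degenerate (zero-variance) cells — routine in noise-free simulations — are
handled explicitly: zero effect over zero error is F = 0, p = 1; a
nonzero effect with zero error is significant.  The same rule applies to
zero-variance paired differences in the post-hoc tests.  Outliers are
reported by the 1.5-IQR whisker convention but never removed.

## Stage 3 — interpretation (`ictrack.interpretation`)

Four refractory-duration estimates are combined: the ANOVA metric, the
unconstrained-intercept estimate (max increase), the constrained-intercept
estimate, and the 5–95% range of RT2 pooled over the interfered ISIs (the
pooling set is a documented choice).  The triggering regime is classified
from the 95% confidence interval of the unconstrained slope against the
three canonical values (−1 external, −1/2 internal-saturated, 0
continuous); overlapping or intermediate cases resolve to "mixed".  An
interior ISI at which mean RT2 strictly exceeds both neighbours (no
plateau or boundary peaks) is reported as a sampling-delay estimate.

## What the synthetic data does and does not emulate

The generator reproduces the paradigm's structure — 1 kHz sampling,
order-specific ISI grids and recovery periods, randomized sessions, the
event-triggered single-channel timing — under an idealized controller:
matched internal model, stationary parameters, optional white observation
noise only.  It does not include signal-dependent motor noise, muscle
dynamics beyond a first-order lag, parameter drift, anticipation or
learning.  Passing tests therefore validate the *analysis chain* (delay
reconstruction and refractoriness statistics recover the generating
controller's parameters and slope laws); they do not certify performance
on human recordings, where model mismatch and non-stationarity add error
sources the noise-recovery test only partially represents.

Reference condition throughout: zero-order system, `Δ_OL` = 0.35 s,
`t_d` = 0.14 s.  Deterministic (noise-free) conditions run with 4 virtual
participants and one repetition per stimulus (32 trials each) — further
replication of identical trials adds nothing; the stochastic saturated
condition uses 200 repetitions per ISI with the event phase stratified
over the open-loop interval, which keeps the per-ISI means within a few
milliseconds of their expectations.  The open-loop-interval sweep
(0.15–0.55 s) uses reversal-only sessions with 3 participants.

## Known limitations

* The internal (threshold-driven) mode with a nonzero threshold is
  implemented but the mapping from noise level and threshold to
  intermediate slopes (between −1 and 0) is not characterized; only the
  saturated limit is pinned by an exact law.
* The delay grid quantizes estimates to 10 ms; continuous-phase event
  trains therefore carry ±5 ms quantization noise per trial (zero-mean,
  negligible after averaging).
* The ANOVA metric is quantized to the experiment's ISI grid and reads
  low by up to one grid gap (e.g. 0.30 s for a 0.35 s interval on the
  zero-order grid); the constrained-fit estimate is grid-free and exact
  under external triggering.
* `rm_anova` requires a complete within-subject design; incomplete cells
  are rejected (with the missing cells listed) rather than imputed.
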