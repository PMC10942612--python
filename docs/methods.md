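# Methods

This note documents the models and numerical choices behind `swimlab`: what
is computed, under which assumptions, and where the design was genuinely
open.

## Oxygen uptake from intermittent-flow traces

An intermittent-flow respirometer alternates a 30-s flush with a 900-s
sealed phase (one 930-s cycle); the first 240 s after each flush are
discarded for mixing equilibration and the remaining 660 s form the
measurement window. Within a window, DO (as a *fraction* of air
saturation) is regressed against time by ordinary least squares and

    MO2 = |slope| · (V_r − V_f) · S_O · 3600 / M_f .

The slope-to-rate conversion as sometimes typeset divides by the
time constant t = 3600 s h⁻¹, which would yield per-second units; the
dimensionally consistent form multiplies by 3600 to express the hourly rate,
and that is what `estimate_mo2` implements. Regressing fraction-saturation
and multiplying by S_O is algebraically identical to regressing mg L⁻¹
directly; only the first form is exposed.

Validity gates: ≥ 100 samples per window (≈1.67 min at 1 Hz, configurable);
windows whose sealed phase cannot host equilibration + measurement are
skipped with a warning; a significantly *positive* slope (t > 2, or exact)
flags the sample as flush-contaminated rather than returning a silently
negative rate. Flush events are located from the explicit `flush` phase
label when present, else from upward DO jumps above a configurable
threshold (default 1 % sat per sample) — the first cycle of an unlabelled
trace is then undetectable by construction, since no preceding decline
exists.

Background (microbial) respiration is the arithmetic mean of the pre- and
post-trial sealed blank rates, subtracted from every estimate; the
background fraction is reported and a warning raised at ≥ 6 % of the fish
rate. Corrected values driven negative are flagged, never clamped.

Water properties come from standard correlations (Benson–Krause solubility,
Kell density, Vogel viscosity), defaulting to fresh water at 28 °C
(S_O ≈ 7.83 mg L⁻¹, ρ ≈ 996 kg m⁻³, μ ≈ 8.33·10⁻⁴ Pa s). The motor
calibration V = 0.06169·RPM − 5.128 is treated as given; its output units
follow the calibration (cm s⁻¹ for the default line) and are never inferred.

## Aerobic performance metrics

* **MO2_rest** — interpolated 20th percentile (type-7/linear convention,
  since "quantile" alone does not fix one) of the estimates within the quiet
  windows of the trial clock, hours 10–18 and 32–51. Taking the quantile
  across both pre-test and late-recovery periods makes the estimate robust
  to residual activity in either.
* **MO2_aggregate** — mean over hours 10–18 (station-holding/aggregating in
  still water).
* **MO2_min, U_opt, MO2_active** — per-speed means over each 10-min step's
  valid windows; the minimum, its speed, and the maximum. "Highest average
  while actively swimming" is read as the highest per-step mean (a rolling
  maximum is deliberately not used; the per-step mean matches how the steps
  are protocolised).
* **U_crit** — Brett's interpolation
  U_last + (t_final/step_duration)·(U_next − U_last).
* **Allometry** — mass-specific rates rescale by (M_meas/M_target)^(1−b)
  with b = 0.7546 (whole-animal exponent from an interspecific fit, taken as
  an input, never re-estimated). Solitary-fish series are rescaled before
  derived metrics; school metrics use mass-specific values directly.
  Tail-beat frequency is never mass-scaled.
* **Curve fits** — configurable family: polynomial (degree ≤ 3) or
  a + b·Uᶜ. On the 14-step schedule a cubic recovers the truth-curve
  minimum to ~0.1 BL s⁻¹.

## EPOC and the partition model

EPOC is the trapezoidal integral of max(MO2 − MO2_rest, 0) on the
window-midpoint time axis, from the end of the U_crit test until the first
estimate ≤ 1.10·MO2_rest or 24 h, whichever comes first, expressed in mg O2
at a standardised per-fish body mass of 1.66 g. Because the first recovery
window's midpoint falls ~10 min after exercise ends (flush + equilibration
dead time), the first measured rate is extended back to t = 0 as a
constant; without this the largest part of the integral is truncated and
the closed-form round-trip cannot hold at 930-s windows. An optional
rolling-median pre-smoother (off by default) damps spontaneous-activity
spikes; the threshold endpoint already limits their leverage.

The partition redistributes EPOC over the speed steps under three
constraints: (1) zero anaerobic contribution below the onset speed
0.5·U_crit (onset fraction configurable); (2) the summed non-aerobic O2
must equal EPOC within 0.09 % relative error; (3) the total-cost curve must
rise smoothly (power/polynomial fit diagnostics, monotonicity and convexity
flags are reported). The modifier's functional form is not constrained
beyond these criteria, so the package declares its own family: a power ramp
`modifier(U) = k·((U − U_on)/U_on)^p` with shape p (default 2) and a single
scale k. k enters linearly, so the conservation equation has a closed-form
solution; it is nevertheless solved by bracketed bisection (auto-expanded
bracket, iteration cap 200, stopping well inside the 0.09 % criterion), and
the closed form serves as an independent oracle in the tests. With EPOC = 0
all modifiers are zero; a positive EPOC with no step above onset is an
error, not a silent zero.

Energy conversions: 3.25 cal per mg O2 and 4.184 J cal⁻¹, so
1 mg O2 kg⁻¹ ≡ 13.6 J kg⁻¹. TEE per step is the hourly rate over the
10-min step (rate/6). COT divides the hourly TEE by speed in km h⁻¹ and
warns at sub-unity (BL s⁻¹) speeds, where COT skews high. TEE per tail
beat divides the hourly TEE by beats per hour (f_TB·3600); the per-minute
convention (·60) seen in some reports is dimensionally inconsistent with an
hourly TEE and is available behind a flag only.

## Kinematics

Coordinate convention: +X downstream, +Y lateral, +Z vertical,
right-handed; angle-to-flow is measured against −X (upstream) and returned
in (−180°, 180°], signed by the lateral component, with a ventral-projection
option (default is the full 3-D angle). The body angle to the frontal
plane is the arccos of the normalised dot product of the peduncle→crosshair
and peduncle→nose vectors — the printed denominator of the original
formulation is not a valid norm product, so the standard vector-angle form
is implemented and validated on synthetic fixtures of known angle.

School length ranks fish by nose position on the flow axis per frame and
measures nose-of-first to peduncle-of-last. Pairwise statistics are
per-frame means/SDs over all unordered nose pairs, averaged over the
sampled frames; sampling a few spaced frames agrees with all-frame averages
on stationary tracks.

Tail-beat frequency uses peak detection (prominence default 20 % of the
signal IQR) over the first 10 beats; amplitude is the mean of five
consecutive crest-to-trough excursions. When a recording contains turns,
the excursion signal is taken over the longest steady-swimming segment
(heading rate ≤ 150 ° s⁻¹ for ≥ 1.5 s) and projected on the lateral axis of
the fish's median heading — mirroring the practice of sampling beats from
steady swimming only.

Turn counting: an event fires when the net heading change across a rolling
1-s span reaches 90°; the detector re-arms below half-threshold
(hysteresis) after a 0.5-s refractory. The span and refractory are design
choices (unspecified in protocol descriptions) set so a tail-beat wobble of
tens of degrees can never register as a turn and a single 95° manoeuvre is
never double-counted under heading jitter.

## The synthetic-data generator

The generator emulates the study conditions, not any particular dataset:

* **Truth curve** MO2(U) = mo2_rest + postural_amp·e^(−U/decay) +
  swim_coef·U^exponent. The decaying term represents postural correction at
  low flow, the power term hydrodynamic cost; the sum gives the
  concave-upward curve with a unique interior minimum. Defaults
  (180, 120, 0.6, 9.0, 2.2) place the minimum at ≈210 mg O2 kg⁻¹ h⁻¹ near
  1.24 BL s⁻¹ and ≈1053 at 8 BL s⁻¹, matching the magnitudes reported for
  a small schooling cyprinid; they were set from those curve landmarks once
  and are exposed, not hard-coded.
* **Phases.** ~19 h quiescent (74 × 930-s cycles) at the zero-speed curve
  value — an aggregating school in still water is active, which reproduces
  the observed ordering aggregate > swimming minimum > resting quantile —
  then 14 × 10-min speed steps (each one 30/570-s cycle with a 120-s
  equilibration and 450-s window, so each step yields one valid window),
  then ~19 h recovery (74 cycles) decaying single-exponentially
  (default amplitude 300 mg O2 kg⁻¹ h⁻¹, τ = 2 h) to the quiescent
  asymptote. Within each recovery cycle the decay is frozen at the
  measurement-window midpoint so every window has an exact scalar truth;
  the induced O(Δt²) discretisation is well inside the 1 % round-trip
  tolerance.
* **DO physics.** Sealed phases decline linearly at
  slope = MO2·M_f/((V_r−V_f)·S_O·3600) fraction-saturation s⁻¹; flushes
  relax exponentially toward 97 % sat with an 8-s mixing constant (only the
  endpoint behaviour, ~95–100 %, is constrained by the protocol; the
  relaxation form is a modelling choice). Gaussian probe noise, default
  0.05 % sat (typical of optical DO probes at 1 Hz), is added per sample.
  Depletion of the chamber raises an error suggesting a shorter sealed
  phase or smaller fish mass.
* **Subject.** Default: an 8-fish school of 1.66-g, 6-cm individuals in a
  9.35-L tunnel at 28 °C. Body length is exposed because the Reynolds
  range of the source experiments under-determines it.
* **Tracks.** Station-holding fish at constant depth with small smoothed
  positional drift (0.5 mm) and vertical jitter (2 mm); base nose offsets
  are rescaled so the mean pairwise distance is exactly the prescribed
  spacing. The tail-beat sinusoid displaces the whole body laterally, so
  heading stays decoupled from the beat — required for the exact
  zero-angle baseline of a solitary non-turning fish — and the peduncle's
  lateral excursion carries the prescribed peak-to-peak amplitude. Turns
  are alternating ±95° smooth ramps (0.24 s) at evenly spaced times.
  Kinematic structure is prescribed, not emergent: no hydrodynamic
  interaction, burst–glide gait, or leader–follower dynamics, so passing
  round-trips validates the measurement code, not schooling behaviour.

## What the tests show (and don't)

Noiseless round-trips are exact to regression precision (<0.1 % per
window); EPOC matches its closed form within 1 % at 930-s windows and ~0.1 %
at 1-Hz sampling; the partition conserves EPOC to ≤ 0.09 % and recovers a
ramp-generated allocation within 10 % when the shape family matches; across
20 noisy replicates at default probe noise the per-speed estimates are
unbiased within 2 %. These validate the estimators under the generator's
assumptions (linear sealed-phase declines, single-exponential recovery,
prescribed kinematics). Real traces add probe drift, temperature
excursions, spontaneous activity and gait transitions that the generator
deliberately omits; the background-correction, flagging and smoothing hooks
exist for those, but their effectiveness on real data is not demonstrated
here.

## Known limitations

* No probe-drift recalibration or within-trial temperature compensation
  (S_O is fixed per trial).
* The partition's ramp family is one admissible choice under the three
  criteria; other shapes satisfying the same constraints would allocate the
  same total differently across steps (the shape exponent is exposed).
* Minimum-over-speeds statistics are biased low under heavy estimate noise
  (a property of the functional, not the estimator); one window per speed
  step keeps this within a fraction of a percent at realistic noise.
* The kinematics module consumes reconstructed coordinates; camera
  calibration and digitisation are out of scope.
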