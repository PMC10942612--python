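# swimlab

Bioenergetics and 3-D kinematics of fish-school locomotion.

`swimlab` is a Python library for analysing swim-tunnel respirometry trials
of schooling fishes (and solitary individuals) over a critical-swimming-speed
(U_crit) protocol, and for quantifying the 3-D kinematics of the school from
reconstructed landmark trajectories. It is aimed at comparative
physiologists and biomechanists who need the full chain from a raw
dissolved-oxygen (DO) trace to total energy expenditure — including the
anaerobic share that aerobic-only respirometry misses — plus a synthetic-data
generator so every stage can be validated against known ground truth.

## What it computes

**Oxygen uptake from intermittent-flow respirometry.** A sealed measurement
window of the flush/closed cycle yields

```
MO2 = |dDO/dt| · (V_r − V_f) · S_O · 3600 / M_f        [mg O2 kg⁻¹ h⁻¹]
```

with dDO/dt the OLS slope of DO (fraction of air saturation) vs time (s),
V_r the respirometer volume, V_f the fish volume (1 g ≡ 1 ml), S_O the O2
solubility at 100 % saturation, and M_f the fish mass.

**Aerobic performance metrics.** Resting rate (quantile-20 % over the quiet
periods of the trial), aggregation rate, the swimming minimum MO2_min and
its optimal speed U_opt (the interior minimum of the concave-upward
MO2–speed curve), the active rate MO2_active, aerobic scope
(MO2_active − MO2_min), %-scope, Brett-interpolated U_crit, allometric mass
rescaling (mass-specific rate × (M_meas/M_target)^(1−b), default b = 0.7546),
and polynomial/power fits of the performance curve.

**EPOC and the aerobic/non-aerobic partition.** Excess post-exercise oxygen
consumption is the integral of recovery MO2 above rest, from the end of the
U_crit test to the rest+10 % endpoint (or 24 h). The partition model
allocates that anaerobic debt back over the speed steps with a percentage
modifier on the aerobic cost, `k·((U − U_on)/U_on)^p` above the onset speed
U_on = 0.5·U_crit and zero below it, with k solved iteratively so the summed
non-aerobic O2 matches EPOC to ≤ 0.09 % relative error. Total O2 cost
converts to TEE (3.25 cal per mg O2) and cost of transport (TEE per km per
kg).

**3-D schooling kinematics.** Pairwise nose–nose distances, school length on
the flow axis, body angle to the frontal plane, angle to flow, tail-beat
frequency and peak-to-peak amplitude, ≥ 90° turning frequency per fish, and
the Strouhal (f·A/U) and Reynolds (ρ·U·L/μ) numbers.

**Synthetic data.** `simulate_trial` builds a ~40 h DO trace (quiescent
phase, 14-step U_crit test at 0.3–8.0 BL s⁻¹, exponential recovery) with a
`TruthRecord` carrying the exact rate behind every window and the analytic
EPOC; `simulate_school_tracks` builds station-holding school trajectories
with prescribed spacing, tail beat and turns.

## Worked example

```python
import swimlab as sl

spec = sl.SimSpec(seed=1)                      # 8-fish school, default truth
trace, truth = sl.simulate_trial(spec)
res = sl.analyze_trial(trace, spec.respirometer, spec.subject,
                       spec.protocol.speed_plan)
print(res.summary)
print(res.epoc)
```

prints (seed 1, default probe noise of 0.05 % sat):

```
EnergeticsSummary(mo2_rest=180.0, mo2_aggregate=299.3, mo2_min=209.4,
                  u_opt=1.0, mo2_active=1051.8, aerobic_scope=842.4,
                  u_crit=8.0)
EpocResult(epoc_mg=0.9478, duration_h=6.11, endpoint_reason='threshold', ...)
```

The school's cheapest speed is ~1 BL s⁻¹ — swimming there costs less than
hovering at zero flow (aggregate 299 mg O2 kg⁻¹ h⁻¹) — and the recovered
minimum/active rates match the generating truth (180 / 209.8 / 1053.1)
within a fraction of a percent. `res.partition.per_speed` then gives the
per-speed aerobic, non-aerobic and total O2 cost, TEE and COT; at the top
speed the total cost is ~3× the aerobic rate alone.

The `examples/` directory holds one short narrative script per capability:
trial simulation, respirometry → energetics, EPOC partitioning, and school
kinematics. Each prints the numbers it computes and what they mean.

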