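"""Synthetic respirometry trials and 3-D school trajectories with known truth.

The generator emulates the study conditions of a swim-tunnel U_crit protocol
on a small schooling cyprinid so that every downstream stage of the pipeline
can be tested against ground truth:

* a ~19 h quiescent/habituation phase of 930-s flush/closed respirometry
  cycles, during which the school aggregates in still water;
* a 14-step incremental swim test (10 min per step, 0.3–8.0 BL s-1) whose
  aerobic rate follows a concave-upward truth curve

      MO2(U) = mo2_rest + postural_amp * exp(-U / postural_decay)
               + swim_coef * U**swim_exponent

  (a decaying postural-correction term plus a super-linear hydrodynamic
  power term, giving a unique interior minimum near 1 BL s-1);
* a ~19 h post-exercise recovery phase whose rate decays single-exponentially
  to the quiescent asymptote, providing a closed-form EPOC.

Dissolved oxygen declines linearly within sealed phases at the slope implied
by the instantaneous truth rate, relaxes exponentially toward the reservoir
saturation during flushes, and carries additive Gaussian probe noise.  The
returned TruthRecord holds the exact rate underlying every measurement window
and the analytic EPOC integral.

School trajectories are prescribed, not emergent: station-holding fish with a
sinusoidal tail-beat excursion, configurable nearest-neighbour spacing,
heading jitter, and a chosen number of discrete >= 90-degree turns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .energetics import SpeedStepPlan
from .respirometry import DOTrace, FlushCyclePlan, RespirometerSpec, SubjectSpec

__all__ = [
    "TruthCurveParams",
    "EpocTruthParams",
    "ProtocolSpec",
    "SimSpec",
    "TruthRecord",
    "mo2_truth",
    "simulate_trial",
    "simulate_school_tracks",
]


@dataclass(frozen=True)
class TruthCurveParams:
    """Parameters of the ground-truth aerobic MO2–speed curve.

    Rates in mg O2 kg-1 h-1, speeds in BL s-1.  Defaults reproduce the
    magnitudes of a giant-danio school: minimum ~210 near 1.25 BL s-1 and
    ~1053 at 8 BL s-1.
    """

    mo2_rest: float = 180.0
    postural_amp: float = 120.0
    postural_decay: float = 0.6
    swim_coef: float = 9.0
    swim_exponent: float = 2.2

    def __post_init__(self) -> None:
        if min(self.mo2_rest, self.postural_amp, self.swim_coef) < 0:
            raise ValueError("rates must be non-negative")
        if self.postural_decay <= 0:
            raise ValueError("postural_decay must be positive")
        if self.swim_exponent <= 1:
            raise ValueError("swim_exponent must exceed 1 (super-linear rise)")


def mo2_truth(params: TruthCurveParams, speed_bls: float | np.ndarray) -> float | np.ndarray:
    """Ground-truth aerobic rate at a swimming speed (closed form above)."""
    speed = np.asarray(speed_bls, float)
    if np.any(speed < 0):
        raise ValueError("speed must be non-negative")
    out = (
        params.mo2_rest
        + params.postural_amp * np.exp(-speed / params.postural_decay)
        + params.swim_coef * np.power(speed, params.swim_exponent)
    )
    return float(out) if np.isscalar(speed_bls) else out


@dataclass(frozen=True)
class EpocTruthParams:
    """Single-exponential recovery: MO2(t) = mo2_rest + amplitude*exp(-t/tau)."""

    amplitude: float = 300.0  # mg O2 kg-1 h-1 above resting at t=0
    tau_h: float = 2.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.tau_h <= 0:
            raise ValueError("amplitude and tau must be positive")


@dataclass(frozen=True)
class ProtocolSpec:
    """Phase plan: rest cycles, speed steps (one cycle each), recovery cycles.

    The quiescent and recovery phases use the standard 930-s cycle; each
    10-min speed step is its own shorter flush/closed cycle (30 s flush,
    120 s equilibration, 450 s measurement) so that one valid window exists
    per step.
    """

    rest_cycles: int = 74
    speed_plan: SpeedStepPlan = field(default_factory=SpeedStepPlan)
    recovery_cycles: int = 74
    rest_plan: FlushCyclePlan = field(default_factory=FlushCyclePlan)
    swim_plan: FlushCyclePlan = field(
        default_factory=lambda: FlushCyclePlan(
            flush_s=30.0, closed_s=570.0, equilibration_s=120.0, measure_s=450.0
        )
    )

    def __post_init__(self) -> None:
        if self.rest_cycles < 1 or self.recovery_cycles < 1:
            raise ValueError("need at least one rest and one recovery cycle")
        if abs(self.swim_plan.cycle_s - self.speed_plan.step_duration_s) > 1e-9:
            raise ValueError(
                "swim cycle (flush+closed) must equal the speed-step duration"
            )


def _default_subject() -> SubjectSpec:
    # An 8-fish school of 1.66 g individuals.
    return SubjectSpec(mass_kg=8 * 0.00166, n_individuals=8, is_school=True)


@dataclass(frozen=True)
class SimSpec:
    """Everything needed to generate one synthetic respirometry trial."""

    respirometer: RespirometerSpec = field(default_factory=RespirometerSpec)
    subject: SubjectSpec = field(default_factory=_default_subject)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    truth: TruthCurveParams = field(default_factory=TruthCurveParams)
    epoc_truth: EpocTruthParams = field(default_factory=EpocTruthParams)
    noise_sd: float = 0.05  # DO probe noise, % saturation
    seed: int = 0
    temp_c: float = 28.0
    flush_target_percent: float = 97.0
    flush_mix_tau_s: float = 8.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated trial.

    ``windows``: DataFrame (start_s, end_s, phase, speed_bls, mo2_true) — the
    exact rate generating each valid measurement window.  ``analytic_epoc_mg``
    is the closed-form integral of the recovery excess above ``mo2_rest_true``
    up to the rest+10 % endpoint, at the standardised mass.
    """

    windows: pd.DataFrame
    mo2_rest_true: float
    per_speed_true: dict[float, float]
    u_opt_true: float
    mo2_min_true: float
    mo2_active_true: float
    u_crit_true: float
    analytic_epoc_mg: float
    epoc_duration_true_h: float

    def to_json(self, path) -> None:
        payload = {
            "windows": self.windows.to_dict(orient="records"),
            "mo2_rest_true": self.mo2_rest_true,
            "per_speed_true": {str(k): v for k, v in self.per_speed_true.items()},
            "u_opt_true": self.u_opt_true,
            "mo2_min_true": self.mo2_min_true,
            "mo2_active_true": self.mo2_active_true,
            "u_crit_true": self.u_crit_true,
            "analytic_epoc_mg": self.analytic_epoc_mg,
            "epoc_duration_true_h": self.epoc_duration_true_h,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def truth_argmin(params: TruthCurveParams, lo: float = 0.0, hi: float = 8.0,
                 du: float = 0.001) -> float:
    """Brute-force grid argmin of the truth curve on [lo, hi]."""
    u = np.arange(lo, hi + du, du)
    return float(u[np.argmin(mo2_truth(params, u))])


def analytic_epoc(epoc_truth: EpocTruthParams, mo2_rest: float,
                  standard_mass_kg: float = 0.00166,
                  threshold_factor: float = 1.10,
                  max_hours: float = 24.0) -> tuple[float, float]:
    """Closed-form EPOC (mg O2) and duration (h) of the exponential recovery.

    Endpoint at MO2 = threshold_factor*rest, i.e. t* = tau*ln(A/((tf-1)*R));
    the integral above rest is A*tau*(1 - exp(-t*/tau)) * mass.
    """
    a, tau = epoc_truth.amplitude, epoc_truth.tau_h
    excess_at_end = (threshold_factor - 1.0) * mo2_rest
    if a <= excess_at_end:
        return 0.0, 0.0
    t_star = tau * np.log(a / excess_at_end)
    t_star = min(t_star, max_hours)
    epoc = standard_mass_kg * a * tau * (1.0 - np.exp(-t_star / tau))
    return float(epoc), float(t_star)


def _do_slope_percent_per_s(mo2: float, resp: RespirometerSpec,
                            subject: SubjectSpec) -> float:
    """DO decline (% sat per s) produced by a given uptake rate."""
    frac_per_s = (
        mo2 * subject.mass_kg
        / (subject.effective_volume_l(resp) * resp.o2_solubility_mg_l * 3600.0)
    )
    return 100.0 * frac_per_s


def simulate_trial(spec: SimSpec) -> tuple[DOTrace, TruthRecord]:
    """Generate a full synthetic trial: rest -> U_crit steps -> recovery.

    Within each sealed phase the DO declines linearly at the slope implied by
    that cycle's truth rate (during recovery, the exponential decay is frozen
    at the cycle's measurement-window midpoint, so each window has an exact
    scalar truth).  Flushes relax DO exponentially toward the reservoir
    saturation.  Gaussian probe noise of sd ``noise_sd`` (% sat) is added to
    every sample.  Raises if the DO would be depleted within a sealed phase.
    """
    resp, subject, proto = spec.respirometer, spec.subject, spec.protocol
    truth, epoc_truth = spec.truth, spec.epoc_truth
    rng = np.random.default_rng(spec.seed)

    times: list[np.ndarray] = []
    dos: list[np.ndarray] = []
    vels: list[np.ndarray] = []
    phases: list[np.ndarray] = []
    win_rows: list[dict] = []

    t_cursor = 0.0
    do_prev = spec.flush_target_percent

    def add_cycle(plan: FlushCyclePlan, phase: str, speed: float,
                  mo2_value: float) -> None:
        nonlocal t_cursor, do_prev
        nf, nc = int(plan.flush_s), int(plan.closed_s)
        # Flush: exponential relaxation toward the reservoir saturation.
        tf = np.arange(1, nf + 1, dtype=float)
        do_f = spec.flush_target_percent + (
            do_prev - spec.flush_target_percent
        ) * np.exp(-tf / spec.flush_mix_tau_s)
        # Sealed: linear decline at the truth rate.
        slope = _do_slope_percent_per_s(mo2_value, resp, subject)
        tc = np.arange(1, nc + 1, dtype=float)
        do_c = do_f[-1] - slope * tc
        if do_c[-1] <= 0:
            raise ValueError(
                "DO would be fully depleted within a sealed phase; use a "
                "shorter closed phase or a smaller fish mass"
            )
        times.append(t_cursor + np.concatenate([tf, plan.flush_s + tc]))
        dos.append(np.concatenate([do_f, do_c]))
        vels.append(np.full(nf + nc, speed))
        ph = np.empty(nf + nc, dtype=object)
        ph[:nf] = "flush"
        ph[nf:] = phase
        phases.append(ph)
        w0 = t_cursor + plan.flush_s + plan.equilibration_s
        win_rows.append(
            {
                "start_s": w0,
                "end_s": w0 + plan.measure_s,
                "phase": phase,
                "speed_bls": speed,
                "mo2_true": mo2_value,
            }
        )
        t_cursor += plan.cycle_s
        do_prev = do_c[-1]

    # Quiescent phase: the school aggregates in still water at the zero-speed
    # curve value (postural/aggregation activity above the resting asymptote).
    mo2_quiet = mo2_truth(truth, 0.0)
    for _ in range(proto.rest_cycles):
        add_cycle(proto.rest_plan, "rest", 0.0, mo2_quiet)

    # Incremental swim test: one short cycle per speed step.
    for u in proto.speed_plan.speeds:
        add_cycle(proto.swim_plan, "swim", float(u), mo2_truth(truth, u))

    # Recovery: exponential decay to the quiescent asymptote, frozen per cycle
    # at the measurement-window midpoint.
    rp = proto.rest_plan
    t_mid_offset = rp.flush_s + rp.equilibration_s + 0.5 * rp.measure_s
    recovery_start = t_cursor
    for i in range(proto.recovery_cycles):
        t_mid_h = (i * rp.cycle_s + t_mid_offset) / 3600.0
        mo2_i = truth.mo2_rest + epoc_truth.amplitude * np.exp(
            -t_mid_h / epoc_truth.tau_h
        )
        add_cycle(rp, "recovery", 0.0, float(mo2_i))

    time_s = np.concatenate(times)
    do = np.concatenate(dos)
    if spec.noise_sd > 0:
        do = do + rng.normal(0.0, spec.noise_sd, size=do.shape)
    df = pd.DataFrame(
        {
            "time_s": time_s,
            "do_percent_sat": np.clip(do, 0.0, 110.0),
            "temp_c": np.full_like(time_s, spec.temp_c),
            "velocity_bls": np.concatenate(vels),
            "phase": np.concatenate(phases),
        }
    )
    trace = DOTrace(df)

    per_speed = {float(u): float(mo2_truth(truth, u)) for u in proto.speed_plan.speeds}
    epoc_mg, epoc_dur = analytic_epoc(epoc_truth, truth.mo2_rest)
    record = TruthRecord(
        windows=pd.DataFrame(win_rows),
        mo2_rest_true=truth.mo2_rest,
        per_speed_true=per_speed,
        u_opt_true=truth_argmin(truth, 0.0, max(proto.speed_plan.speeds)),
        mo2_min_true=min(per_speed.values()),
        mo2_active_true=max(per_speed.values()),
        u_crit_true=float(proto.speed_plan.speeds[-1]),
        analytic_epoc_mg=epoc_mg,
        epoc_duration_true_h=epoc_dur,
    )
    # Stash the recovery-phase origin for downstream EPOC clocks.
    record.windows.attrs["recovery_start_s"] = recovery_start
    return trace, record


def _smoothed_noise(rng: np.random.Generator, shape: tuple[int, ...],
                    sigma_frames: float, sd: float) -> np.ndarray:
    """Gaussian noise low-pass filtered along axis 0 and rescaled to ``sd``."""
    if sd <= 0:
        return np.zeros(shape)
    x = gaussian_filter1d(rng.standard_normal(shape), sigma_frames, axis=0)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_school_tracks(
    n_fish: int,
    speed_bls: float = 1.0,
    ftb_hz: float = 5.0,
    amplitude_m: float = 0.012,
    nnd_bl: float = 1.2,
    heading_sd_deg: float = 0.0,
    n_turns: int = 0,
    duration_s: float = 10.0,
    fps: float = 125.0,
    seed: int = 0,
    body_length_m: float = 0.06,
    turn_deg: float = 95.0,
    pitch_deg: float = 0.0,
    drift_sd_m: float = 0.0005,
    z_jitter_sd_m: float = 0.002,
):
    """Prescribed station-holding school trajectories in the flume frame.

    Fish hold position against the flow (+X downstream); the tail-beat is a
    lateral sinusoid of peak-to-peak ``amplitude_m`` at ``ftb_hz`` displacing
    the whole body (so the body-axis heading stays decoupled from the beat,
    and the peduncle's lateral excursion carries the beat signal).  Base nose
    positions are scaled so the mean pairwise nose distance equals
    ``nnd_bl`` body lengths.  ``n_turns`` discrete heading changes of
    ``turn_deg`` >= 90 degrees (alternating sign) are inserted per fish at
    evenly spaced times.  Returns a :class:`~swimlab.kinematics.Track3D`.
    """
    from .kinematics import Track3D  # local import to avoid a cycle

    if n_fish < 1:
        raise ValueError("need at least one fish")
    if fps <= 2.0 * ftb_hz:
        raise ValueError(
            f"fps={fps} too low for ftb={ftb_hz} Hz (need fps > 2*ftb)"
        )
    if turn_deg < 90.0:
        raise ValueError("inserted turns must be >= 90 degrees")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * fps))
    t = np.arange(n_frames) / fps

    # Base school layout: random offsets rescaled to the target mean spacing.
    if n_fish > 1:
        from scipy.spatial.distance import pdist

        offsets = rng.uniform(-0.5, 0.5, size=(n_fish, 3))
        offsets[:, 2] *= 0.3  # schools are flatter vertically
        d0 = pdist(offsets).mean()
        offsets *= nnd_bl * body_length_m / d0
    else:
        offsets = np.zeros((1, 3))

    # Heading: smoothed jitter plus alternating discrete turns.
    heading = _smoothed_noise(rng, (n_frames, n_fish), 0.1 * fps, heading_sd_deg)
    if n_turns > 0:
        spacing = duration_s / (n_turns + 1)
        ramp_s = 0.24
        if spacing < ramp_s + 1.5:
            raise ValueError(
                "turns too dense: spacing must exceed the ramp plus the "
                "detector span/refractory (~1.7 s)"
            )
        for k in range(n_turns):
            tk = (k + 1) * spacing
            step = np.clip((t - tk) / ramp_s, 0.0, 1.0)
            heading += ((-1.0) ** k) * turn_deg * step[:, None]
    theta = np.radians(heading)

    # Whole-body lateral tail-beat displacement, per-fish phase.
    phase0 = rng.uniform(0, 2 * np.pi, size=n_fish)
    s = 0.5 * amplitude_m * np.sin(2 * np.pi * ftb_hz * t[:, None] + phase0[None, :])

    drift = _smoothed_noise(rng, (n_frames, n_fish, 3), 1.0 * fps, drift_sd_m)
    z_jit = _smoothed_noise(rng, (n_frames, n_fish), 1.0 * fps, z_jitter_sd_m)

    # Unit vectors: body direction (into the flow at heading 0) and lateral.
    d_hat = np.stack([-np.cos(theta), np.sin(theta)], axis=-1)  # (F, N, 2)
    l_hat = np.stack([np.sin(theta), np.cos(theta)], axis=-1)

    nose = np.empty((n_frames, n_fish, 3))
    nose[:, :, 0] = offsets[None, :, 0] + drift[:, :, 0] + s * l_hat[:, :, 0]
    nose[:, :, 1] = offsets[None, :, 1] + drift[:, :, 1] + s * l_hat[:, :, 1]
    nose[:, :, 2] = offsets[None, :, 2] + drift[:, :, 2] + z_jit

    pitch = np.radians(pitch_deg)
    body = np.empty_like(nose)
    body[:, :, 0] = body_length_m * np.cos(pitch) * d_hat[:, :, 0]
    body[:, :, 1] = body_length_m * np.cos(pitch) * d_hat[:, :, 1]
    body[:, :, 2] = body_length_m * np.sin(pitch)
    ped = nose - body

    cross = nose.copy()
    cross[:, :, 2] = ped[:, :, 2]  # right-angle projection at peduncle depth

    coords = np.stack([nose, ped, cross], axis=2)
    return Track3D(coords, fps=fps)
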