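"""Oxygen-uptake estimation from intermittent-flow respirometry traces.

An intermittent-flow swim-tunnel respirometer alternates short flush phases
(fresh, air-saturated water pumped through the chamber) with longer sealed
phases during which the dissolved-oxygen (DO) level declines as the fish
consume O2.  Whole-animal oxygen uptake over a sealed measurement window is

    MO2 = |dDO/dt| * (V_r - V_f) * S_O * 3600 / M_f      [mg O2 kg-1 h-1]

where dDO/dt is the ordinary-least-squares slope of DO (as a fraction of air
saturation) against time in seconds, V_r the respirometer volume (L), V_f the
fish volume (L; 1 g body mass displaces 1 ml), S_O the O2 solubility of the
water at 100 % saturation (mg L-1), M_f the fish mass (kg), and 3600 the
seconds-per-hour constant that puts the rate on an hourly basis.

The module segments a labelled DO trace into valid measurement windows
(discarding the equilibration period after every flush), regresses each
window, applies background (microbial) respiration correction, and converts
motor RPM to water velocity via a linear calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .water import o2_solubility

__all__ = [
    "RespirometerSpec",
    "SubjectSpec",
    "FlushCyclePlan",
    "DOTrace",
    "MO2Sample",
    "MeasurementWindow",
    "segment_cycles",
    "estimate_mo2",
    "mo2_series",
    "correct_background",
    "rpm_to_velocity",
    "SECONDS_PER_HOUR",
]

SECONDS_PER_HOUR = 3600.0

#: Default motor-RPM -> water-velocity calibration (slope, intercept), from a
#: PIV-validated linear fit for the 9.35 L swim tunnel; output units follow the
#: calibration (cm s-1 for the default coefficients).
DEFAULT_RPM_CALIBRATION = (0.06169, -5.128)


@dataclass(frozen=True)
class RespirometerSpec:
    """Respirometer geometry and water chemistry.

    Attributes
    ----------
    volume_l : total respirometer volume V_r (L), tubing included.
    o2_solubility_mg_l : S_O, mg O2 per L at 100 % air saturation.  Defaults
        to fresh water at 28 degC.
    rpm_calibration : (slope, intercept) of the linear RPM->velocity line.
    """

    volume_l: float = 9.35
    o2_solubility_mg_l: float = field(default_factory=lambda: o2_solubility(28.0))
    rpm_calibration: tuple[float, float] = DEFAULT_RPM_CALIBRATION

    def __post_init__(self) -> None:
        if self.volume_l <= 0:
            raise ValueError("respirometer volume must be positive")
        if self.o2_solubility_mg_l <= 0:
            raise ValueError("O2 solubility must be positive")


@dataclass(frozen=True)
class SubjectSpec:
    """The fish (individual or whole school) inside the chamber.

    ``volume_l`` defaults to mass in kg interpreted as litres (1 g ~ 1 ml of
    displaced water).  ``mass_kg`` is the *total* mass in the chamber; for a
    school it is the sum over individuals.
    """

    mass_kg: float
    volume_l: float | None = None
    n_individuals: int = 1
    fork_length_m: float = 0.06
    is_school: bool = False

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError("fish mass must be positive")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if self.fork_length_m <= 0:
            raise ValueError("fork length must be positive")
        if self.volume_l is None:
            object.__setattr__(self, "volume_l", self.mass_kg)  # 1 g == 1 ml
        if self.volume_l <= 0:
            raise ValueError("fish volume must be positive")

    def effective_volume_l(self, resp: RespirometerSpec) -> float:
        v = resp.volume_l - self.volume_l
        if v <= 0:
            raise ValueError("fish volume exceeds respirometer volume")
        return v


@dataclass(frozen=True)
class FlushCyclePlan:
    """Timing of one flush/closed respirometry cycle (seconds).

    The default 930-s cycle: 30 s flush, 900 s sealed; the first 240 s of the
    sealed phase are discarded (mixing equilibration) and the remaining 660 s
    form the measurement window.
    """

    flush_s: float = 30.0
    closed_s: float = 900.0
    equilibration_s: float = 240.0
    measure_s: float = 660.0

    def __post_init__(self) -> None:
        if min(self.flush_s, self.closed_s, self.equilibration_s, self.measure_s) < 0:
            raise ValueError("cycle durations must be non-negative")
        if self.equilibration_s + self.measure_s > self.closed_s:
            raise ValueError(
                "equilibration_s + measure_s must not exceed the closed phase"
            )

    @property
    def cycle_s(self) -> float:
        return self.flush_s + self.closed_s


TRACE_COLUMNS = ["time_s", "do_percent_sat", "temp_c", "velocity_bls", "phase"]


class DOTrace:
    """A timestamped dissolved-oxygen record (~1 Hz) with a velocity channel.

    Wraps a DataFrame with columns ``time_s, do_percent_sat, temp_c,
    velocity_bls, phase``; ``phase`` is one of ``flush | rest | swim |
    recovery`` (flush samples are labelled explicitly).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"DOTrace missing columns: {missing}")
        t = df["time_s"].to_numpy(float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing")
        do = df["do_percent_sat"].to_numpy(float)
        if len(do) and (do.min() < 0 or do.max() > 110):
            raise ValueError("DO must lie in [0, 110] % saturation")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path) -> "DOTrace":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class MeasurementWindow:
    """A sealed-phase span used for one MO2 regression."""

    start_s: float
    end_s: float
    phase: str
    speed_bls: float


@dataclass(frozen=True)
class MO2Sample:
    """One oxygen-uptake estimate from a sealed measurement window."""

    start_s: float
    end_s: float
    mo2: float  # mg O2 kg-1 h-1
    r_squared: float
    phase: str
    speed_bls: float
    flagged: bool = False

    @property
    def t_mid_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


def _flush_blocks(trace: DOTrace, do_jump_threshold: float) -> list[tuple[int, int]]:
    """Index spans [i0, i1) of flush events, from labels or DO upward jumps."""
    df = trace.df
    phase = df["phase"].astype(str).to_numpy()
    is_flush = phase == "flush"
    if not is_flush.any():
        # Fallback: steep upward DO jumps mark flushing.
        ddo = np.diff(df["do_percent_sat"].to_numpy(float), prepend=np.nan)
        is_flush = ddo > do_jump_threshold
    blocks: list[tuple[int, int]] = []
    i = 0
    n = len(df)
    while i < n:
        if is_flush[i]:
            j = i
            while j < n and is_flush[j]:
                j += 1
            blocks.append((i, j))
            i = j
        else:
            i += 1
    return blocks


def segment_cycles(
    trace: DOTrace,
    plan: FlushCyclePlan,
    phases: Sequence[str] | None = None,
    do_jump_threshold: float = 1.0,
) -> list[MeasurementWindow]:
    """Locate the valid measurement window of every flush/closed cycle.

    Each window spans ``[flush_end + equilibration_s, flush_end +
    equilibration_s + measure_s]``.  A sealed phase too short to host the full
    window (trace truncated, or the next flush starts early) yields no window
    and a warning.  ``phases`` optionally restricts to windows whose sealed
    phase carries one of the given labels.
    """
    df = trace.df
    t = df["time_s"].to_numpy(float)
    blocks = _flush_blocks(trace, do_jump_threshold)
    if not blocks:
        raise ValueError("no flush events found (no 'flush' labels or DO jumps)")
    windows: list[MeasurementWindow] = []
    phase_col = df["phase"].astype(str).to_numpy()
    for k, (i0, i1) in enumerate(blocks):
        if i1 >= len(df):
            break
        flush_end = t[i1 - 1]  # last flush sample; sealed phase starts next
        cycle_phase = phase_col[i1]
        if phases is not None and cycle_phase not in phases:
            continue
        w0 = flush_end + plan.equilibration_s
        w1 = w0 + plan.measure_s
        # Sealed phase ends at the next flush (or end of trace).
        next_start = t[blocks[k + 1][0]] if k + 1 < len(blocks) else t[-1]
        if w1 > next_start:
            warnings.warn(
                f"cycle at t={flush_end:.0f}s: sealed phase shorter than "
                f"equilibration+measure ({plan.equilibration_s + plan.measure_s:.0f}s)"
                " - window skipped",
                stacklevel=2,
            )
            continue
        sel = (t >= w0) & (t <= w1)
        seg = df.loc[sel]
        if seg.empty:
            continue
        speed = float(seg["velocity_bls"].mean())
        windows.append(MeasurementWindow(w0, w1, str(cycle_phase), speed))
    return windows


def estimate_mo2(
    window: pd.DataFrame,
    resp: RespirometerSpec,
    subject: SubjectSpec,
    min_samples: int = 100,
    phase: str = "",
    speed_bls: float = 0.0,
) -> MO2Sample:
    """Regress DO against time over one sealed window and convert to MO2.

    DO is regressed as a *fraction* of saturation; the OLS slope (fraction per
    second), respirometer net volume, solubility, the 3600 s h-1 constant and
    fish mass give mg O2 kg-1 h-1.  A significantly positive slope (DO rising
    while sealed, e.g. flush contamination) flags the sample rather than
    producing a silently negative rate.
    """
    if len(window) < min_samples:
        raise ValueError(
            f"window has {len(window)} samples; need >= {min_samples} for a "
            "stable regression"
        )
    t = window["time_s"].to_numpy(float)
    do_frac = window["do_percent_sat"].to_numpy(float) / 100.0
    fit = stats.linregress(t, do_frac)
    slope = fit.slope  # fraction sat per second
    # Rising DO while sealed (flush contamination): flag when the positive
    # slope is significant (t > 2) or exact (zero residual).
    flagged = bool(slope > 0 and (fit.stderr == 0 or slope / fit.stderr > 2.0))
    mo2 = (
        -slope
        * subject.effective_volume_l(resp)
        * resp.o2_solubility_mg_l
        * SECONDS_PER_HOUR
        / subject.mass_kg
    )
    return MO2Sample(
        start_s=float(t[0]),
        end_s=float(t[-1]),
        mo2=float(mo2),
        r_squared=float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0,
        phase=phase,
        speed_bls=speed_bls,
        flagged=flagged,
    )


def mo2_series(
    trace: DOTrace,
    windows: Iterable[MeasurementWindow],
    resp: RespirometerSpec,
    subject: SubjectSpec,
    min_samples: int = 100,
) -> pd.DataFrame:
    """Estimate MO2 for every window; returns the MO2Series DataFrame.

    Columns: ``window_start_s, window_end_s, t_mid_s, phase, speed_bls,
    mo2_mgO2_kg_h, r2, flagged``.
    """
    df = trace.df
    t = df["time_s"].to_numpy(float)
    rows = []
    for w in windows:
        sel = (t >= w.start_s) & (t <= w.end_s)
        sample = estimate_mo2(
            df.loc[sel], resp, subject, min_samples=min_samples,
            phase=w.phase, speed_bls=w.speed_bls,
        )
        rows.append(
            {
                "window_start_s": sample.start_s,
                "window_end_s": sample.end_s,
                "t_mid_s": sample.t_mid_s,
                "phase": sample.phase,
                "speed_bls": sample.speed_bls,
                "mo2_mgO2_kg_h": sample.mo2,
                "r2": sample.r_squared,
                "flagged": sample.flagged,
            }
        )
    return pd.DataFrame(rows)


def correct_background(
    series: pd.DataFrame,
    pre_bg: float,
    post_bg: float,
    warn_fraction: float = 0.06,
) -> tuple[pd.DataFrame, float]:
    """Subtract mean microbial (background) respiration from every estimate.

    Background is measured in the sealed, fish-free chamber before and after
    the trial; the arithmetic mean of the two rates is subtracted.  Returns
    the corrected series and ``bg_fraction`` (background / mean fish MO2);
    warns when the fraction reaches ``warn_fraction`` (default 6 %).  Samples
    driven negative by the correction are flagged, never clamped.
    """
    if pre_bg < 0 or post_bg < 0:
        raise ValueError("background rates must be non-negative")
    bg = 0.5 * (pre_bg + post_bg)
    mean_mo2 = float(series["mo2_mgO2_kg_h"].mean())
    if bg > mean_mo2:
        raise ValueError(
            f"background rate ({bg:.1f}) exceeds mean fish MO2 ({mean_mo2:.1f}); "
            "non-physical - check chamber cleaning or probe drift"
        )
    bg_fraction = bg / mean_mo2 if mean_mo2 > 0 else 0.0
    if bg_fraction >= warn_fraction:
        warnings.warn(
            f"background respiration is {100 * bg_fraction:.1f}% of fish MO2 "
            f"(>= {100 * warn_fraction:.0f}%)",
            stacklevel=2,
        )
    out = series.copy()
    out["mo2_mgO2_kg_h"] = out["mo2_mgO2_kg_h"] - bg
    out["flagged"] = out["flagged"] | (out["mo2_mgO2_kg_h"] < 0)
    return out, bg_fraction


def rpm_to_velocity(rpm: float, resp: RespirometerSpec | None = None) -> float:
    """Convert motor RPM to water velocity via the linear calibration.

    With the default coefficients, ``V = 0.06169 * RPM - 5.128`` in the
    calibration's velocity units.  RPM below the zero-velocity crossing is
    rejected.
    """
    slope, intercept = (
        resp.rpm_calibration if resp is not None else DEFAULT_RPM_CALIBRATION
    )
    v = slope * rpm + intercept
    if v < 0:
        raise ValueError(
            f"RPM {rpm} is below the zero-velocity point ({-intercept / slope:.2f})"
        )
    return v
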