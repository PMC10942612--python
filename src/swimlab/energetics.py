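"""Aerobic performance metrics from a per-window oxygen-uptake series.

Definitions follow standard swim-tunnel practice for a critical-swimming-speed
(U_crit) protocol:

* ``MO2_rest`` — quantile-20 % of the estimates within designated quiet
  periods of the trial (a robust floor estimate of maintenance metabolism);
* ``MO2_aggregate`` — mean rate during the pre-test quiescent period, when a
  school holds station and interacts in still water;
* ``MO2_min`` and ``U_opt`` — the lowest per-speed mean during swimming and
  the speed attaining it (the energetic optimum of the concave-upward
  MO2–speed curve);
* ``MO2_active`` — highest per-speed mean while actively swimming;
* aerobic scope — ``MO2_active − MO2_min``; %-scope rescales any rate onto
  that envelope;
* ``U_crit`` — Brett's interpolation into the final, incomplete speed step.

Solitary-fish rates are allometrically rescaled to a target body mass (shared
mass-scaling exponent b) before school/solitary comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AllometryParams",
    "SpeedStepPlan",
    "EnergeticsSummary",
    "FittedCurve",
    "DEFAULT_QUIET_WINDOWS_H",
    "allometric_scale",
    "mo2_rest",
    "mo2_aggregate",
    "per_speed_means",
    "summarize_energetics",
    "percent_scope",
    "percent_reduction",
    "compute_ucrit",
    "fit_mo2_speed_curve",
]

#: Quiet (quiescent-state) periods of the standard ~40 h trial used for the
#: resting-rate quantile: hours 10–18 (pre-test) and 32–51 (post-recovery).
DEFAULT_QUIET_WINDOWS_H: tuple[tuple[float, float], ...] = ((10.0, 18.0), (32.0, 51.0))

#: Pre-test quiescent window used for the aggregation rate, hours 10–18.
DEFAULT_AGGREGATE_WINDOW_H: tuple[float, float] = (10.0, 18.0)


@dataclass(frozen=True)
class AllometryParams:
    """Whole-animal metabolic mass-scaling: log10(MO2) = b*log10(M) + log_a."""

    b: float = 0.7546
    log_a: float = 0.2046
    source_note: str = "interspecific least-squares fit, 180 points, related cyprinid"

    def __post_init__(self) -> None:
        if not (0.0 < self.b < 1.2):
            raise ValueError("scaling exponent b must lie in (0, 1.2)")


@dataclass(frozen=True)
class SpeedStepPlan:
    """Incremental U_crit speed schedule (BL s-1) with fixed step duration."""

    speeds: tuple[float, ...] = (
        0.3, 0.5, 0.8, 1.0, 1.3, 1.5, 1.8, 2.3, 2.8, 3.8, 4.9, 5.9, 6.9, 8.0,
    )
    step_duration_s: float = 600.0

    def __post_init__(self) -> None:
        if len(self.speeds) < 1:
            raise ValueError("need at least one speed step")
        if np.any(np.diff(self.speeds) <= 0):
            raise ValueError("speeds must be strictly increasing")
        if self.step_duration_s <= 0:
            raise ValueError("step duration must be positive")


@dataclass(frozen=True)
class EnergeticsSummary:
    """Aerobic performance-curve metrics, all rates in mg O2 kg-1 h-1."""

    mo2_rest: float
    mo2_aggregate: float
    mo2_min: float
    u_opt: float
    mo2_active: float
    aerobic_scope: float
    u_crit: float

    def __post_init__(self) -> None:
        if self.mo2_min > self.mo2_active + 1e-9:
            raise ValueError("mo2_min must not exceed mo2_active")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EnergeticsSummary":
        with open(path) as fh:
            return cls(**json.load(fh))


def allometric_scale(
    mo2: float | np.ndarray,
    m_measured_kg: float,
    m_target_kg: float,
    params: AllometryParams = AllometryParams(),
) -> float | np.ndarray:
    """Rescale a mass-specific rate measured at one body mass to another.

    Whole-animal rate scales as M**b, so the mass-specific rate scales as
    M**(b-1) and the transform is ``mo2 * (m_measured / m_target)**(1 - b)``.
    Composes: A->B then B->C equals A->C.
    """
    if m_measured_kg <= 0 or m_target_kg <= 0:
        raise ValueError("masses must be positive")
    return mo2 * (m_measured_kg / m_target_kg) ** (1.0 - params.b)


def _values_in_hours(series: pd.DataFrame,
                     windows_h: Sequence[tuple[float, float]]) -> np.ndarray:
    t_h = series["t_mid_s"].to_numpy(float) / 3600.0
    mo2 = series["mo2_mgO2_kg_h"].to_numpy(float)
    mask = np.zeros(len(series), dtype=bool)
    for lo, hi in windows_h:
        mask |= (t_h >= lo) & (t_h <= hi)
    if "flagged" in series:
        mask &= ~series["flagged"].to_numpy(bool)
    return mo2[mask]


def mo2_rest(
    series: pd.DataFrame,
    quiet_windows_h: Sequence[tuple[float, float]] = DEFAULT_QUIET_WINDOWS_H,
    quantile: float = 0.20,
    min_samples: int = 10,
) -> float:
    """Resting rate: interpolated 20th percentile within the quiet windows.

    The linear-interpolation (type-7) quantile convention is used.
    """
    vals = _values_in_hours(series, quiet_windows_h)
    if len(vals) < min_samples:
        raise ValueError(
            f"only {len(vals)} estimates fall in the quiet windows; "
            f"need >= {min_samples}"
        )
    return float(np.quantile(vals, quantile))  # numpy default = linear / type 7


def mo2_aggregate(
    series: pd.DataFrame,
    window_h: tuple[float, float] = DEFAULT_AGGREGATE_WINDOW_H,
) -> float:
    """Mean rate over the pre-test quiescent window (aggregating behaviour)."""
    vals = _values_in_hours(series, [window_h])
    if len(vals) == 0:
        raise ValueError(f"no estimates fall inside the window {window_h} h")
    return float(vals.mean())


def per_speed_means(series: pd.DataFrame, phase: str = "swim") -> pd.DataFrame:
    """Mean MO2 per speed step (valid, unflagged windows only)."""
    sel = series[(series["phase"] == phase) & ~series["flagged"].astype(bool)]
    if sel.empty:
        raise ValueError(f"no unflagged windows with phase={phase!r}")
    out = (
        sel.groupby("speed_bls", as_index=False)["mo2_mgO2_kg_h"]
        .mean()
        .sort_values("speed_bls", ignore_index=True)
    )
    return out


def summarize_energetics(
    series: pd.DataFrame,
    plan: SpeedStepPlan,
    u_crit: float,
    quiet_windows_h: Sequence[tuple[float, float]] = DEFAULT_QUIET_WINDOWS_H,
    aggregate_window_h: tuple[float, float] = DEFAULT_AGGREGATE_WINDOW_H,
) -> EnergeticsSummary:
    """Assemble the aerobic performance metrics from a full-trial MO2 series.

    ``mo2_min``/``u_opt`` are the minimum per-speed mean and its speed;
    ``mo2_active`` the maximum per-speed mean during swimming (the "highest
    average when actively swimming" convention — per-step means, not a rolling
    maximum).
    """
    speed_means = per_speed_means(series)
    if len(speed_means) < 3:
        raise ValueError("need at least 3 speed steps to summarise the curve")
    mo2_by_speed = speed_means.set_index("speed_bls")["mo2_mgO2_kg_h"]
    u_opt = float(mo2_by_speed.idxmin())
    summary = EnergeticsSummary(
        mo2_rest=mo2_rest(series, quiet_windows_h),
        mo2_aggregate=mo2_aggregate(series, aggregate_window_h),
        mo2_min=float(mo2_by_speed.min()),
        u_opt=u_opt,
        mo2_active=float(mo2_by_speed.max()),
        aerobic_scope=float(mo2_by_speed.max() - mo2_by_speed.min()),
        u_crit=float(u_crit),
    )
    return summary


def percent_scope(mo2: float | np.ndarray, summary: EnergeticsSummary) -> float | np.ndarray:
    """Rate as a percentage of aerobic scope: (MO2-min)/(active-min)*100.

    May exceed 100 % for transient estimates above ``mo2_active``.
    """
    if summary.aerobic_scope <= 0:
        raise ValueError("aerobic scope is zero; %-scope undefined")
    return (mo2 - summary.mo2_min) / summary.aerobic_scope * 100.0


def percent_reduction(higher: float, lower: float) -> float:
    """Percentage reduction of ``lower`` relative to ``higher`` (100*(h-l)/h)."""
    if higher <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (higher - lower) / higher


def compute_ucrit(
    plan: SpeedStepPlan,
    last_completed_index: int,
    time_in_final_step_s: float = 0.0,
) -> float:
    """Brett's interpolated critical swimming speed.

    ``U_crit = U_last + (t_final / step_duration) * (U_next − U_last)`` where
    ``U_last`` is the last fully completed step and ``t_final`` the time swum
    into the step at which the fish fatigued.  A fish completing the whole
    schedule has ``U_crit`` equal to the top speed.
    """
    speeds = plan.speeds
    if not (0 <= last_completed_index < len(speeds)):
        raise ValueError("last_completed_index outside the speed schedule")
    if not (0.0 <= time_in_final_step_s <= plan.step_duration_s):
        raise ValueError("time_in_final_step_s outside [0, step_duration]")
    u_last = speeds[last_completed_index]
    if last_completed_index == len(speeds) - 1:
        return float(u_last)
    u_next = speeds[last_completed_index + 1]
    frac = time_in_final_step_s / plan.step_duration_s
    return float(u_last + frac * (u_next - u_last))


@dataclass(frozen=True)
class FittedCurve:
    """A fitted MO2–speed (or total-cost–speed) curve with diagnostics."""

    family: str  # "polynomial" or "power"
    coefficients: tuple[float, ...]
    r_squared: float
    predict: Callable[[np.ndarray], np.ndarray]

    def minimum(self, lo: float, hi: float, grid: int = 20001) -> tuple[float, float]:
        """Grid-refined location and value of the curve minimum on [lo, hi]."""
        u = np.linspace(lo, hi, grid)
        y = self.predict(u)
        i = int(np.argmin(y))
        return float(u[i]), float(y[i])


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_mo2_speed_curve(
    per_speed: pd.DataFrame | Sequence[tuple[float, float]],
    family: str = "polynomial",
    degree: int = 3,
) -> FittedCurve:
    """Least-squares fit of the per-speed means.

    ``family='polynomial'`` fits a degree-``degree`` (<= 3) polynomial;
    ``family='power'`` fits ``a + b * U**c`` (non-linear, Levenberg–Marquardt
    via scipy).  At least five points are required.
    """
    if isinstance(per_speed, pd.DataFrame):
        u = per_speed["speed_bls"].to_numpy(float)
        y = per_speed["mo2_mgO2_kg_h"].to_numpy(float)
    else:
        arr = np.asarray(per_speed, float)
        u, y = arr[:, 0], arr[:, 1]
    if len(u) < 5:
        raise ValueError("need at least 5 per-speed points to fit the curve")
    if family == "polynomial":
        if not (1 <= degree <= 3):
            raise ValueError("polynomial degree must be 1..3")
        coefs = np.polyfit(u, y, degree)
        poly = np.poly1d(coefs)
        yhat = poly(u)
        return FittedCurve(
            family="polynomial",
            coefficients=tuple(float(c) for c in coefs),
            r_squared=_r_squared(y, yhat),
            predict=lambda x, _p=poly: _p(np.asarray(x, float)),
        )
    if family == "power":
        from scipy.optimize import curve_fit

        def model(x, a, b, c):
            return a + b * np.power(np.maximum(x, 1e-12), c)

        p0 = (float(y.min()), max(float(y.max() - y.min()), 1.0) / max(u.max(), 1.0) ** 2, 2.0)
        popt, _ = curve_fit(model, u, y, p0=p0, maxfev=20000)
        yhat = model(u, *popt)
        return FittedCurve(
            family="power",
            coefficients=tuple(float(c) for c in popt),
            r_squared=_r_squared(y, yhat),
            predict=lambda x, _p=tuple(popt): model(np.asarray(x, float), *_p),
        )
    raise ValueError(f"unknown curve family {family!r}")
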