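"""End-to-end analysis of one swim-tunnel trial.

Chains the stages: segment the DO trace into measurement windows, regress
each window into an oxygen-uptake estimate, summarise the aerobic
performance curve, integrate EPOC over the recovery phase, and partition the
total cost of swimming into aerobic and non-aerobic components.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .energetics import (
    EnergeticsSummary,
    SpeedStepPlan,
    compute_ucrit,
    per_speed_means,
    summarize_energetics,
)
from .epoc import EpocResult, PartitionResult, compute_epoc, fit_nonaerobic_partition
from .respirometry import (
    DOTrace,
    FlushCyclePlan,
    RespirometerSpec,
    SubjectSpec,
    mo2_series,
    segment_cycles,
)

__all__ = ["TrialAnalysis", "analyze_trial"]


@dataclass
class TrialAnalysis:
    """All derived results of one trial."""

    series: pd.DataFrame  # MO2Series over the whole trial
    summary: EnergeticsSummary
    epoc: EpocResult
    partition: PartitionResult


def analyze_trial(
    trace: DOTrace,
    resp: RespirometerSpec,
    subject: SubjectSpec,
    plan: SpeedStepPlan,
    rest_plan: FlushCyclePlan | None = None,
    swim_plan: FlushCyclePlan | None = None,
    last_completed_index: int | None = None,
    time_in_final_step_s: float = 0.0,
    onset_frac: float = 0.5,
    shape_p: float = 2.0,
) -> TrialAnalysis:
    """Run the full respirometry -> energetics -> EPOC -> partition pipeline.

    ``rest_plan`` (default standard 930-s cycle) segments the quiescent and
    recovery phases; ``swim_plan`` (default 30 s flush / 120 s equilibration /
    450 s measurement within each 10-min step) segments the speed steps.  A
    fish that completed the whole schedule needs no ``last_completed_index``.
    """
    rest_plan = rest_plan or FlushCyclePlan()
    swim_plan = swim_plan or FlushCyclePlan(
        flush_s=30.0, closed_s=plan.step_duration_s - 30.0,
        equilibration_s=120.0,
        measure_s=plan.step_duration_s - 30.0 - 120.0,
    )
    quiet_windows = segment_cycles(trace, rest_plan, phases=("rest", "recovery"))
    swim_windows = segment_cycles(trace, swim_plan, phases=("swim",))
    min_swim = min(100, int(swim_plan.measure_s) // 2)
    series = pd.concat(
        [
            mo2_series(trace, quiet_windows, resp, subject),
            mo2_series(trace, swim_windows, resp, subject, min_samples=min_swim),
        ],
        ignore_index=True,
    ).sort_values("window_start_s", ignore_index=True)

    if last_completed_index is None:
        last_completed_index = len(plan.speeds) - 1
    u_crit = compute_ucrit(plan, last_completed_index, time_in_final_step_s)
    summary = summarize_energetics(series, plan, u_crit)

    # Recovery clock starts at the end of the U_crit test.
    swim_mask = trace.df["phase"] == "swim"
    recovery_start_s = float(trace.df.loc[swim_mask, "time_s"].max())
    recovery = series[series["phase"] == "recovery"].copy()
    recovery["t_mid_s"] = recovery["t_mid_s"] - recovery_start_s
    epoc = compute_epoc(recovery, summary.mo2_rest)

    partition = fit_nonaerobic_partition(
        per_speed_means(series),
        u_crit=u_crit,
        epoc=epoc,
        step_duration_s=plan.step_duration_s,
        onset_frac=onset_frac,
        shape_p=shape_p,
        body_length_m=subject.fork_length_m,
    )
    return TrialAnalysis(series=series, summary=summary, epoc=epoc,
                         partition=partition)
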