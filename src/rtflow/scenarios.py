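"""Vacation scenarios, baseline calibration, metrics and suite comparison.

A vacation scenario is a weeks-long window of percentage capacity reduction
applied to the treatment stage, with the preparation stage's equally long
window optionally starting some weeks earlier.  The nine-scenario summer
suite (period lengths 8/6/4 weeks, reductions 30/50/70%, offsets 0–4 weeks)
ships as a packaged fixture and is the default what-if battery.

Scenario quality is summarised by three quantities managers trade off: the
peak number of prepared patients waiting to start treatment (the "ready
queue"), total overtime (fraction-units delivered above capacity to keep
ongoing courses uninterrupted) and total idle linac capacity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import DepartmentConfig, SimulationResult, run
from .referrals import ReferralSchedule

__all__ = [
    "VacationScenario",
    "ScenarioMetrics",
    "SuiteResult",
    "table1_suite",
    "load_scenario_suite",
    "compute_metrics",
    "calibrate_baseline",
    "run_suite",
    "CalibrationError",
]

#: Default placement of the treatment vacation in a 70-week horizon starting
#: in January: week 27 falls at the turn of June/July.
DEFAULT_TREAT_START_WEEK = 27


@dataclass(frozen=True)
class VacationScenario:
    """One capacity-reduction policy: window length, depths and timing.

    ``prep_offset_weeks`` is how many weeks *before* the treatment vacation
    the preparation vacation starts (both windows share the same length).
    """

    scenario_id: str
    length_weeks: int
    prep_reduction: float
    treat_reduction: float
    prep_offset_weeks: int = 0
    treat_start_week: int = DEFAULT_TREAT_START_WEEK

    def __post_init__(self) -> None:
        if self.length_weeks < 1:
            raise ValueError("length_weeks must be >= 1")
        for name in ("prep_reduction", "treat_reduction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.prep_offset_weeks < 0:
            raise ValueError("prep_offset_weeks must be >= 0")

    @property
    def treat_weeks(self) -> range:
        return range(self.treat_start_week, self.treat_start_week + self.length_weeks)

    @property
    def prep_weeks(self) -> range:
        start = self.treat_start_week - self.prep_offset_weeks
        return range(start, start + self.length_weeks)


def _suite_from_records(records: list[dict], treat_start_week: int) -> list[VacationScenario]:
    return [
        VacationScenario(treat_start_week=treat_start_week, **rec) for rec in records
    ]


def table1_suite(treat_start_week: int = DEFAULT_TREAT_START_WEEK) -> list[VacationScenario]:
    """The nine packaged summer-vacation scenarios, placed in the horizon."""
    text = resources.files("rtflow.data").joinpath("table1_scenarios.json").read_text()
    return _suite_from_records(json.loads(text), treat_start_week)


def load_scenario_suite(
    path: str | Path, treat_start_week: int = DEFAULT_TREAT_START_WEEK
) -> list[VacationScenario]:
    """Load a scenario suite from a JSON list of VacationScenario field maps."""
    records = json.loads(Path(path).read_text())
    return _suite_from_records(records, treat_start_week)


@dataclass
class ScenarioMetrics:
    """Summary quantities of one scenario run.

    Peak, overtime and idle totals are read over ``analysis_weeks`` (by
    default the vacation episode plus the pre/post windows, so the empty-
    system warm-up and unrelated late-horizon fluctuations are excluded);
    the weekly overtime/idle series cover the whole horizon.
    """

    scenario_id: str
    peak_ready_queue: float
    week_of_peak: int
    total_overtime: float
    overtime_by_week: pd.Series
    total_idle: float
    idle_by_week: pd.Series
    mean_treat_utilization_pre: float
    mean_treat_utilization_during: float
    mean_treat_utilization_post: float
    analysis_weeks: tuple[int, int] = (1, 10**9)

    def overtime_in_week(self, week: int) -> float:
        return float(self.overtime_by_week.get(week, 0.0))

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "peak_ready_queue": self.peak_ready_queue,
            "week_of_peak": self.week_of_peak,
            "total_overtime": self.total_overtime,
            "total_idle": self.total_idle,
            "mean_treat_utilization_pre": self.mean_treat_utilization_pre,
            "mean_treat_utilization_during": self.mean_treat_utilization_during,
            "mean_treat_utilization_post": self.mean_treat_utilization_post,
        }


def _window_utilization(weekly: pd.DataFrame, weeks: list[int]) -> float:
    weeks = [w for w in weeks if w in weekly.index]
    if not weeks:
        return float("nan")
    sub = weekly.loc[weeks]
    cap = float(sub["treat_capacity"].sum())
    return float(sub["fractions_delivered"].sum()) / cap if cap > 0 else 0.0


def compute_metrics(
    result: SimulationResult,
    scenario: VacationScenario,
    pre_weeks: int = 4,
    post_weeks: int = 4,
    analysis_weeks: tuple[int, int] | None = None,
) -> ScenarioMetrics:
    """Summarise one run: peak ready queue, overtime/idle, window utilizations.

    ``analysis_weeks`` (inclusive week range) bounds where the peak and the
    overtime/idle totals are read; it defaults to the vacation episode —
    ``[prep-window start − pre_weeks, treatment-window end + post_weeks]`` —
    so the pre-vacation weeks act as warm-up and late-horizon fluctuations
    unrelated to the scenario are excluded.  Utilization (delivered
    fraction-units over available units; exceeds 1 under overtime) is
    reported for the treatment-vacation weeks and the ``pre_weeks`` /
    ``post_weeks`` windows on either side.
    """
    if scenario.treat_weeks.stop - 1 > result.horizon_weeks:
        raise ValueError("scenario window outside the simulated horizon")
    during = list(scenario.treat_weeks)
    pre = list(range(scenario.treat_start_week - pre_weeks, scenario.treat_start_week))
    post = list(range(during[-1] + 1, during[-1] + 1 + post_weeks))
    if analysis_weeks is None:
        analysis_weeks = (
            max(1, scenario.prep_weeks.start - pre_weeks),
            min(result.horizon_weeks, during[-1] + post_weeks),
        )
    lo, hi = analysis_weeks

    daily = result.frame
    window = daily[(daily["week"] >= lo) & (daily["week"] <= hi)]
    if window.empty:
        raise ValueError("analysis window outside the simulated horizon")
    peak_idx = int(window["ready_to_start"].idxmax())
    weekly = result.weekly()
    return ScenarioMetrics(
        scenario_id=scenario.scenario_id,
        peak_ready_queue=float(window["ready_to_start"].max()),
        week_of_peak=int(window["week"].loc[peak_idx]),
        total_overtime=float(window["overtime_units"].sum()),
        overtime_by_week=weekly["overtime_units"],
        total_idle=float(window["idle_units"].sum()),
        idle_by_week=weekly["idle_units"],
        mean_treat_utilization_pre=_window_utilization(weekly, pre),
        mean_treat_utilization_during=_window_utilization(weekly, during),
        mean_treat_utilization_post=_window_utilization(weekly, post),
        analysis_weeks=(lo, hi),
    )


class CalibrationError(RuntimeError):
    pass


def _queue_is_stable(
    schedule: ReferralSchedule,
    config: DepartmentConfig,
    part: str,
    tolerance: float,
) -> bool:
    """No-vacation run; True if the part's queue is not persistently growing.

    The relevant queue is awaiting-prep for the preparation part and the
    ready-to-start queue for the treatment part; stability means the terminal
    weekly level does not exceed the mid-horizon level by more than
    ``tolerance`` patients.
    """
    column = "awaiting_prep" if part == "prep" else "ready_to_start"
    weekly = run(schedule, config).weekly()[column]
    mid = float(weekly.iloc[len(weekly) // 2])
    return float(weekly.iloc[-1]) <= mid + tolerance


def calibrate_baseline(
    schedule: ReferralSchedule,
    config: DepartmentConfig,
    part: str,
    tolerance: float = 1.0,
    resolution: float = 1.0,
    max_capacity: float | None = None,
) -> float:
    """Lowest capacity (on a ``resolution`` grid) not building a persistent queue.

    Bisection over the chosen part's baseline capacity on a no-vacation run;
    the other part keeps the template's value.  Raises
    :class:`CalibrationError` if even ``max_capacity`` cannot stabilise the
    queue.
    """
    if part not in ("prep", "treat"):
        raise ValueError("part must be 'prep' or 'treat'")
    field_name = "prep_capacity_per_week" if part == "prep" else "treat_capacity_per_day"

    def stable(capacity: float) -> bool:
        cfg = replace(config, **{field_name: capacity})
        return _queue_is_stable(schedule, cfg, part, tolerance)

    if stable(0.0):
        return 0.0
    if max_capacity is None:
        # generous upper bound: clear the busiest week's load in one week/day
        arrivals = schedule.arrivals_matrix()
        peak_week = float(arrivals.sum(axis=1).max()) if arrivals.size else 1.0
        if part == "prep":
            max_capacity = 4.0 * max(peak_week, 1.0)
        else:
            unit_demand = float(
                (arrivals * (schedule.fraction_counts() + config.first_fraction_weight - 1.0)).sum(axis=1).max()
            )
            max_capacity = 4.0 * max(unit_demand, 1.0)
    hi_steps = int(np.ceil(max_capacity / resolution))
    if not stable(hi_steps * resolution):
        raise CalibrationError(
            f"{part} capacity {hi_steps * resolution} still builds a persistent "
            f"queue (tolerance {tolerance}); inflow may exceed any stable level"
        )
    lo, hi = 0, hi_steps  # lo fails, hi passes
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if stable(mid * resolution):
            hi = mid
        else:
            lo = mid
    return hi * resolution


@dataclass
class SuiteResult:
    """Metrics table and rankings for a set of scenarios on one schedule."""

    metrics: pd.DataFrame  # indexed by scenario_id, sorted
    scenario_metrics: dict[str, ScenarioMetrics]
    results: dict[str, SimulationResult] = field(default_factory=dict)

    @property
    def rankings(self) -> dict[str, list[str]]:
        return {
            "peak_ready_queue": list(self.metrics.sort_values("peak_ready_queue").index),
            "total_overtime": list(self.metrics.sort_values("total_overtime").index),
            "total_idle": list(self.metrics.sort_values("total_idle").index),
        }

    def to_markdown(self) -> str:
        lines = ["# Scenario comparison", "", self.metrics.round(2).to_markdown(), ""]
        for key, order in self.rankings.items():
            lines.append(f"- best (lowest) {key}: {', '.join(order)}")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "metrics": {sid: m.to_dict() for sid, m in self.scenario_metrics.items()},
            "rankings": self.rankings,
        }


def run_suite(
    schedule: ReferralSchedule,
    config: DepartmentConfig,
    scenarios: list[VacationScenario],
    pre_weeks: int = 4,
    post_weeks: int = 4,
    keep_results: bool = True,
) -> SuiteResult:
    """Run every scenario on the same schedule/config and tabulate metrics.

    The output is sorted by scenario id, so it is invariant to the order the
    scenarios are passed in.
    """
    metrics: dict[str, ScenarioMetrics] = {}
    results: dict[str, SimulationResult] = {}
    for scen in scenarios:
        res = run(schedule, config, scen)
        metrics[scen.scenario_id] = compute_metrics(res, scen, pre_weeks, post_weeks)
        if keep_results:
            results[scen.scenario_id] = res
    table = (
        pd.DataFrame([m.to_dict() for m in metrics.values()])
        .set_index("scenario_id")
        .sort_index()
    )
    return SuiteResult(metrics=table, scenario_metrics=metrics, results=results)
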