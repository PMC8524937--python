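"""Deterministic stock-and-flow simulator of the radiotherapy process.

The department is modelled as two capacity-limited stages on a working-day
clock (5 treatment days per week by default):

* a **preparation** stage (mould, imaging, contouring, planning and QA
  combined) modelled as a fixed-delay conveyor: capacity limits how many
  patients *enter* preparation each day, and everyone who enters exits ready
  to start treatment exactly ``prep_lead_working_days`` later (8 working days
  ≈ the typical 1.5-week span);
* a **treatment** stage (the linac park) modelled as an aging chain indexed
  by remaining fractions.  Daily capacity is expressed in fraction-units; the
  first fraction of a course consumes ``first_fraction_weight`` units
  (default 2: extra time for patient information and technical verification).

Treatment starts as soon as a prepared patient fits in today's residual
linac capacity.  Ongoing treatment courses are never interrupted: when
ongoing demand exceeds the day's capacity the excess is booked as overtime;
unused capacity is booked as idle.  All stocks are real-valued (continuous
flows), so the dynamics are built from min, + and × only — which makes the
model exactly conservative and positively homogeneous.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .referrals import ReferralSchedule

if TYPE_CHECKING:  # avoid a circular import; scenarios imports this module
    from .scenarios import VacationScenario

__all__ = [
    "DepartmentConfig",
    "CapacityProfile",
    "SimState",
    "StepRecord",
    "SimulationResult",
    "build_capacity_profile",
    "step",
    "run",
]

_EPS = 1e-12


@dataclass(frozen=True)
class DepartmentConfig:
    """Baseline capacities and calendar conventions of the department.

    Defaults are a large-department setting: 100 patients/week preparation
    throughput, 330 fraction-units/day on the linacs, an 8-working-day
    preparation lead (≈1.5 five-day weeks) and a double-weight first fraction.
    """

    prep_capacity_per_week: float = 100.0
    treat_capacity_per_day: float = 330.0
    treatment_days_per_week: int = 5
    prep_lead_working_days: int = 8
    first_fraction_weight: float = 2.0

    def __post_init__(self) -> None:
        if self.prep_capacity_per_week < 0 or self.treat_capacity_per_day < 0:
            raise ValueError("capacities must be >= 0")
        if not 1 <= self.treatment_days_per_week <= 7:
            raise ValueError("treatment_days_per_week must be in 1..7")
        if self.prep_lead_working_days < 1:
            raise ValueError("prep_lead_working_days must be >= 1")
        if self.first_fraction_weight < 1:
            raise ValueError("first_fraction_weight must be >= 1")


@dataclass
class CapacityProfile:
    """Per-working-day capacity series (prep in patients, treat in units)."""

    prep_per_day: np.ndarray
    treat_per_day: np.ndarray

    def __post_init__(self) -> None:
        self.prep_per_day = np.asarray(self.prep_per_day, dtype=float)
        self.treat_per_day = np.asarray(self.treat_per_day, dtype=float)
        if len(self.prep_per_day) != len(self.treat_per_day):
            raise ValueError("capacity series must have equal length")
        if (self.prep_per_day < 0).any() or (self.treat_per_day < 0).any():
            raise ValueError("capacities must be >= 0")

    @property
    def n_days(self) -> int:
        return len(self.prep_per_day)


def build_capacity_profile(
    config: DepartmentConfig,
    scenario: "VacationScenario | None",
    horizon_weeks: int,
) -> CapacityProfile:
    """Expand baseline capacities into daily series with vacation reductions.

    The treatment vacation covers weeks ``[treat_start_week,
    treat_start_week + length)``; the preparation vacation has the same
    length and starts ``prep_offset_weeks`` earlier.  Reductions apply to all
    working days of those weeks.  Weeks are 1-based.
    """
    dpw = config.treatment_days_per_week
    n_days = horizon_weeks * dpw
    prep = np.full(n_days, config.prep_capacity_per_week / dpw)
    treat = np.full(n_days, config.treat_capacity_per_day)
    if scenario is not None and (scenario.prep_reduction or scenario.treat_reduction):
        t0 = scenario.treat_start_week
        p0 = t0 - scenario.prep_offset_weeks
        length = scenario.length_weeks
        for start, name in ((p0, "preparation"), (t0, "treatment")):
            if start < 1 or start + length - 1 > horizon_weeks:
                raise ValueError(
                    f"{name} vacation window (weeks {start}..{start + length - 1}) "
                    f"outside the {horizon_weeks}-week horizon"
                )
        prep_days = slice((p0 - 1) * dpw, (p0 - 1 + length) * dpw)
        treat_days = slice((t0 - 1) * dpw, (t0 - 1 + length) * dpw)
        prep[prep_days] *= 1.0 - scenario.prep_reduction
        treat[treat_days] *= 1.0 - scenario.treat_reduction
    return CapacityProfile(prep_per_day=prep, treat_per_day=treat)


@dataclass
class _ReadyBucket:
    day: int  # working day the patients completed preparation
    counts: np.ndarray  # per-group patient mass


@dataclass
class SimState:
    """Mutable per-group stocks of the running simulation.

    ``conveyor[d]`` holds the prep cohort exiting in ``d + 1`` days;
    ``chain[r]`` holds the in-treatment mass whose remaining fraction count
    (after today's delivery) is ``r`` — the ``r = 0`` cohort received its
    last fraction today and is moved to ``completed`` at the start of the
    next treatment phase.  Pooled groups may carry fractional representative
    fraction counts; their starters' mass is split between the two adjacent
    integer remaining slots so that expected fractions per patient equal the
    group's ``n_fractions`` exactly.
    """

    group_fractions: np.ndarray
    first_fraction_weight: float
    awaiting: np.ndarray
    conveyor: np.ndarray
    ready: deque = field(default_factory=deque)
    chain: np.ndarray = None  # type: ignore[assignment]
    completed: np.ndarray = None  # type: ignore[assignment]
    arrived: np.ndarray = None  # type: ignore[assignment]
    started_treatment: np.ndarray = None  # type: ignore[assignment]
    fractions_given: np.ndarray = None  # type: ignore[assignment]

    @classmethod
    def initial(
        cls, group_fractions: Sequence[float], config: DepartmentConfig
    ) -> "SimState":
        f = np.asarray(group_fractions, dtype=float)
        if (f < 1).any():
            raise ValueError("every group needs n_fractions >= 1")
        n = len(f)
        slots = int(math.ceil(max(f.max() - 1.0, 0.0))) + 1 if n else 1
        return cls(
            group_fractions=f,
            first_fraction_weight=config.first_fraction_weight,
            awaiting=np.zeros(n),
            conveyor=np.zeros((config.prep_lead_working_days, n)),
            ready=deque(),
            chain=np.zeros((slots, n)),
            completed=np.zeros(n),
            arrived=np.zeros(n),
            started_treatment=np.zeros(n),
            fractions_given=np.zeros(n),
        )

    @property
    def ready_total(self) -> float:
        return float(sum(b.counts.sum() for b in self.ready))

    def stocks(self) -> dict[str, float]:
        return {
            "awaiting_prep": float(self.awaiting.sum()),
            "in_prep": float(self.conveyor.sum()),
            "ready_to_start": self.ready_total,
            "in_treatment": float(self.chain.sum()),
            "completed": float(self.completed.sum()),
        }

    def _check_nonnegative(self) -> None:
        for arr in (self.awaiting, self.conveyor, self.chain, self.completed):
            if (arr < -1e-9).any():
                raise RuntimeError("internal consistency error: negative stock")
            np.maximum(arr, 0.0, out=arr)


@dataclass
class StepRecord:
    """Flows and stock totals of one working day."""

    day: int
    week: int
    prep_starts: float
    prep_completions: float
    treatment_starts: float
    fractions_delivered: float  # fraction-units (first fraction weighted)
    overtime_units: float
    idle_units: float
    prep_capacity: float
    treat_capacity: float
    awaiting_prep: float
    in_prep: float
    ready_to_start: float
    in_treatment: float
    completed: float
    cumulative_arrivals: float
    # fraction bookkeeping: given + still owed == committed (n_fractions per
    # starter), an exact per-step conservation identity
    fractions_given_cum: float
    fractions_owed: float
    fractions_committed: float


def step(
    state: SimState,
    day: int,
    arrivals_today: np.ndarray,
    prep_capacity: float,
    treat_capacity: float,
    treatment_days_per_week: int = 5,
) -> tuple[SimState, StepRecord]:
    """Advance the system by one working day (mutates and returns ``state``).

    Order of events: arrivals join the awaiting-prep stock; prep starts
    min(awaiting, prep capacity) patients, allocated proportionally across
    groups, while the conveyor advances and its front exits to the ready
    queue; finished-yesterday treatment mass moves to completed; all ongoing
    courses receive their fraction unconditionally (excess over capacity is
    overtime); the residual capacity admits new starts FIFO by
    prep-completion day (proportional across groups within a day), each
    consuming ``first_fraction_weight`` units; leftover capacity is idle.
    """
    w = state.first_fraction_weight

    # 1. referrals arrive
    state.awaiting += arrivals_today
    state.arrived += arrivals_today

    # 2. preparation stage: capacity limits conveyor entry
    total_wait = float(state.awaiting.sum())
    prep_starts = min(total_wait, prep_capacity)
    if prep_starts > _EPS:
        start_vec = state.awaiting * (prep_starts / total_wait)
        state.awaiting -= start_vec
    else:
        prep_starts = 0.0
        start_vec = np.zeros_like(state.awaiting)
    completions = state.conveyor[0].copy()
    state.conveyor[:-1] = state.conveyor[1:]
    state.conveyor[-1] = start_vec
    prep_completions = float(completions.sum())
    if prep_completions > _EPS:
        state.ready.append(_ReadyBucket(day=day, counts=completions))

    # 3. treatment stage: finishers out, ongoing served, chain ages
    state.completed += state.chain[0]
    ongoing_by_group = state.chain[1:].sum(axis=0)
    ongoing = float(ongoing_by_group.sum())
    state.chain[:-1] = state.chain[1:]
    state.chain[-1] = 0.0
    overtime = max(0.0, ongoing - treat_capacity)
    residual = max(0.0, treat_capacity - ongoing)

    # 4. new treatment starts, FIFO by prep-completion day
    need = min(state.ready_total, residual / w)
    starts_vec = np.zeros_like(state.awaiting)
    remaining = need
    while remaining > _EPS and state.ready:
        bucket = state.ready[0]
        btot = float(bucket.counts.sum())
        if btot <= remaining + _EPS:
            starts_vec += bucket.counts
            remaining -= btot
            state.ready.popleft()
        else:
            take = bucket.counts * (remaining / btot)
            starts_vec += take
            bucket.counts = bucket.counts - take
            remaining = 0.0
    starts = float(starts_vec.sum())
    state.started_treatment += starts_vec
    if starts > _EPS:
        rem = state.group_fractions - 1.0  # subsequent fractions per patient
        lo = np.floor(rem).astype(int)
        theta = rem - lo
        np.add.at(state.chain, (lo, np.arange(len(rem))), starts_vec * (1.0 - theta))
        hi_mask = theta > _EPS
        if hi_mask.any():
            idx = np.arange(len(rem))[hi_mask]
            np.add.at(state.chain, (lo[hi_mask] + 1, idx), starts_vec[hi_mask] * theta[hi_mask])

    delivered = ongoing + w * starts
    idle = max(0.0, treat_capacity - ongoing - w * starts)
    state.fractions_given += ongoing_by_group + starts_vec
    state._check_nonnegative()

    owed = float(np.arange(state.chain.shape[0]) @ state.chain.sum(axis=1))
    record = StepRecord(
        day=day,
        week=day // treatment_days_per_week + 1,
        prep_starts=prep_starts,
        prep_completions=prep_completions,
        treatment_starts=starts,
        fractions_delivered=delivered,
        overtime_units=overtime,
        idle_units=idle,
        prep_capacity=prep_capacity,
        treat_capacity=treat_capacity,
        cumulative_arrivals=float(state.arrived.sum()),
        fractions_given_cum=float(state.fractions_given.sum()),
        fractions_owed=owed,
        fractions_committed=float(state.group_fractions @ state.started_treatment),
        **state.stocks(),
    )
    return state, record


@dataclass
class SimulationResult:
    """Trajectories and per-group totals of one simulation run."""

    frame: pd.DataFrame  # one row per working day, StepRecord columns
    horizon_weeks: int
    config: DepartmentConfig
    scenario: "VacationScenario | None"
    group_ids: list[str]
    group_fractions: np.ndarray
    completed_by_group: np.ndarray
    started_by_group: np.ndarray
    fractions_by_group: np.ndarray
    final_state: SimState | None = None

    def weekly(self) -> pd.DataFrame:
        """Aggregate the daily frame to weeks (sums for flows, last for stocks)."""
        flows = [
            "prep_starts", "prep_completions", "treatment_starts",
            "fractions_delivered", "overtime_units", "idle_units",
            "prep_capacity", "treat_capacity",
        ]
        stocks = [
            "awaiting_prep", "in_prep", "ready_to_start", "in_treatment",
            "completed", "cumulative_arrivals",
        ]
        agg = {c: "sum" for c in flows} | {c: "last" for c in stocks}
        out = self.frame.groupby("week").agg(agg)
        out["treat_utilization"] = np.where(
            out["treat_capacity"] > 0,
            out["fractions_delivered"] / out["treat_capacity"],
            0.0,
        )
        return out

    def to_long_frame(self) -> pd.DataFrame:
        """Long CSV layout: day, week, metric, group_id, value."""
        melted = self.frame.melt(
            id_vars=["day", "week"], var_name="metric", value_name="value"
        )
        melted["group_id"] = "ALL"
        melted = melted[["day", "week", "metric", "group_id", "value"]]
        return melted.sort_values(["day", "metric", "group_id"], kind="stable").reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def run(
    schedule: ReferralSchedule,
    config: DepartmentConfig,
    scenario: "VacationScenario | None" = None,
    profile: CapacityProfile | None = None,
    keep_state: bool = False,
) -> SimulationResult:
    """Simulate the full horizon (weekly arrivals on each week's first day)."""
    if profile is None:
        profile = build_capacity_profile(config, scenario, schedule.horizon_weeks)
    dpw = config.treatment_days_per_week
    if profile.n_days != schedule.horizon_weeks * dpw:
        raise ValueError("capacity profile length does not match the horizon")

    arrivals = schedule.arrivals_matrix()
    n_groups = arrivals.shape[1]
    state = SimState.initial(schedule.fraction_counts(), config)
    zero = np.zeros(n_groups)

    records = []
    for day in range(profile.n_days):
        week, weekday = divmod(day, dpw)
        today = arrivals[week] if weekday == 0 else zero
        _, rec = step(
            state, day, today,
            profile.prep_per_day[day], profile.treat_per_day[day],
            treatment_days_per_week=dpw,
        )
        records.append(rec)

    frame = pd.DataFrame([r.__dict__ for r in records])
    return SimulationResult(
        frame=frame,
        horizon_weeks=schedule.horizon_weeks,
        config=config,
        scenario=scenario,
        group_ids=schedule.group_ids,
        group_fractions=schedule.fraction_counts(),
        completed_by_group=state.completed.copy(),
        started_by_group=state.started_treatment.copy(),
        fractions_by_group=state.fractions_given.copy(),
        final_state=state if keep_state else None,
    )
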