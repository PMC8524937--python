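"""Stock-flow engine: capacity profiles, step rules, conservation, oracle checks."""

import numpy as np
import pytest

import rtflow as rf
from _oracle import oracle_run
from conftest import make_reference_schedule


def scenario(sid="S", length=8, prep=0.3, treat=0.3, offset=0, start=27):
    return rf.VacationScenario(
        scenario_id=sid, length_weeks=length, prep_reduction=prep,
        treat_reduction=treat, prep_offset_weeks=offset, treat_start_week=start,
    )


class TestCapacityProfile:
    def test_no_vacation_is_flat_baseline(self, dept):
        profile = rf.build_capacity_profile(dept, None, 10)
        np.testing.assert_allclose(profile.prep_per_day, 20.0)
        np.testing.assert_allclose(profile.treat_per_day, 330.0)

    def test_simultaneous_30pct_reduction_values(self, dept):
        profile = rf.build_capacity_profile(dept, scenario(), 70)
        inside = slice(26 * 5, 34 * 5)
        np.testing.assert_allclose(profile.prep_per_day[inside], 14.0)
        np.testing.assert_allclose(profile.treat_per_day[inside], 231.0)
        np.testing.assert_allclose(profile.prep_per_day[: 26 * 5], 20.0)
        np.testing.assert_allclose(profile.treat_per_day[34 * 5:], 330.0)

    def test_offset_prep_window_ends_when_treatment_window_begins(self, dept):
        scen = scenario(length=4, prep=0.7, treat=0.7, offset=4)
        profile = rf.build_capacity_profile(dept, scen, 70)
        prep_reduced = np.flatnonzero(profile.prep_per_day < 20.0)
        treat_reduced = np.flatnonzero(profile.treat_per_day < 330.0)
        assert prep_reduced[-1] + 1 == treat_reduced[0]

    def test_window_outside_horizon_rejected(self, dept):
        with pytest.raises(ValueError):
            rf.build_capacity_profile(dept, scenario(start=68), 70)


class TestStep:
    def test_null_step(self, dept):
        state = rf.SimState.initial([5.0], dept)
        _, rec = rf.step(state, 0, np.zeros(1), 20.0, 330.0)
        assert rec.prep_starts == rec.treatment_starts == rec.fractions_delivered == 0
        assert rec.idle_units == 330.0 and rec.overtime_units == 0.0

    def test_first_fraction_weight_limits_starts(self, dept):
        """4 ready patients, capacity 6, weight 2 -> 3 starts, 6 units, 1 left."""
        state = rf.SimState.initial([3.0], dept)
        state.ready.append(rf.engine._ReadyBucket(day=0, counts=np.array([4.0])))
        _, rec = rf.step(state, 1, np.zeros(1), 0.0, 6.0)
        assert rec.treatment_starts == pytest.approx(3.0)
        assert rec.fractions_delivered == pytest.approx(6.0)
        assert rec.ready_to_start == pytest.approx(1.0)
        assert state.chain[2, 0] == pytest.approx(3.0)  # remaining 2 of 3 fractions

    def test_ongoing_demand_served_as_overtime(self, dept):
        """Ongoing demand 10 against capacity 8: never interrupted, overtime 2."""
        state = rf.SimState.initial([5.0], dept)
        state.chain[3, 0] = 10.0
        _, rec = rf.step(state, 0, np.zeros(1), 0.0, 8.0)
        assert rec.fractions_delivered == pytest.approx(10.0)
        assert rec.overtime_units == pytest.approx(2.0)
        assert rec.treatment_starts == 0.0 and rec.idle_units == 0.0


class TestRunExtremes:
    def test_zero_inflow_everything_idle(self, dept):
        sched = rf.generate_constant_schedule(1, 10, 5)
        sched.groups[0].weekly_counts = np.zeros(10)
        res = rf.run(sched, dept)
        f = res.frame
        assert (f["fractions_delivered"] == 0).all()
        assert (f["idle_units"] == f["treat_capacity"]).all()
        assert (f[["awaiting_prep", "ready_to_start", "in_treatment", "completed"]] == 0).all().all()

    def test_zero_treat_capacity_blocks_downstream_only(self):
        cfg = rf.DepartmentConfig(prep_capacity_per_week=1000, treat_capacity_per_day=0)
        sched = rf.generate_constant_schedule(10, 10, 5)
        res = rf.run(sched, cfg)
        f = res.frame
        assert (f["treatment_starts"] == 0).all()
        cum_completions = f["prep_completions"].cumsum()
        np.testing.assert_allclose(f["ready_to_start"], cum_completions, atol=1e-9)

    def test_high_inflow_queues_grow_but_conserve(self, dept):
        sched = rf.generate_constant_schedule(10000, 10, 20)
        res = rf.run(sched, dept)
        f = res.frame
        assert f["awaiting_prep"].iloc[-1] > f["awaiting_prep"].iloc[20]
        _assert_conserved(f, atol=1e-6)


def _assert_conserved(frame, atol):
    stocks = (
        frame["awaiting_prep"] + frame["in_prep"] + frame["ready_to_start"]
        + frame["in_treatment"] + frame["completed"]
    )
    np.testing.assert_allclose(stocks, frame["cumulative_arrivals"], atol=atol, rtol=0)
    np.testing.assert_allclose(
        frame["fractions_given_cum"] + frame["fractions_owed"],
        frame["fractions_committed"], atol=atol, rtol=0,
    )
    np.testing.assert_allclose(
        frame["fractions_delivered"],
        frame["treat_capacity"] - frame["idle_units"] + frame["overtime_units"],
        atol=atol, rtol=0,
    )


def test_littles_law_steady_state(dept):
    """Constant inflow λ/week, F fractions, ample capacity: stock = λF/5."""
    cfg = rf.DepartmentConfig(prep_capacity_per_week=1000, treat_capacity_per_day=1000)
    res = rf.run(rf.generate_constant_schedule(10, 30, 5), cfg)
    tail = res.frame["in_treatment"].iloc[60:]
    np.testing.assert_allclose(tail, 10 * 5 / 5, atol=1e-6)


def test_fraction_conservation_on_completion():
    """Once everything drains, delivered fractions = completed × n_fractions,
    including a pooled group with a fractional representative count."""
    counts = np.zeros(30)
    counts[:5] = 7.0
    groups = [
        rf.WorkflowGroup("a|curative", "a", "curative", 23.0, counts),
        rf.WorkflowGroup("other|palliative", "other", "palliative", 4.6, counts * 0.5),
    ]
    sched = rf.ReferralSchedule(groups=groups, horizon_weeks=30)
    cfg = rf.DepartmentConfig(prep_capacity_per_week=500, treat_capacity_per_day=500)
    res = rf.run(sched, cfg)
    np.testing.assert_allclose(res.completed_by_group, [35.0, 17.5], atol=1e-9)
    np.testing.assert_allclose(
        res.fractions_by_group, res.completed_by_group * res.group_fractions, atol=1e-9
    )


def test_conservation_on_random_instances():
    rng = np.random.default_rng(123)
    for _ in range(10):
        n_groups = rng.integers(1, 6)
        weeks = int(rng.integers(4, 15))
        groups = [
            rf.WorkflowGroup(
                f"g{i}", f"g{i}", "curative",
                float(rng.uniform(1.0, 20.0)),
                rng.uniform(0, 8, size=weeks),
            )
            for i in range(n_groups)
        ]
        sched = rf.ReferralSchedule(groups=groups, horizon_weeks=weeks)
        cfg = rf.DepartmentConfig(
            prep_capacity_per_week=float(rng.uniform(1, 40)),
            treat_capacity_per_day=float(rng.uniform(1, 60)),
        )
        res = rf.run(sched, cfg)
        _assert_conserved(res.frame, atol=1e-9)


def test_positive_homogeneity():
    """Scaling arrivals and both capacities by k scales every trajectory by k."""
    sched = make_reference_schedule(1)
    cfg = rf.DepartmentConfig()
    base = rf.run(sched, cfg, scenario()).frame
    cols = ["prep_starts", "prep_completions", "treatment_starts", "fractions_delivered",
            "overtime_units", "idle_units", "awaiting_prep", "in_prep",
            "ready_to_start", "in_treatment", "completed"]
    for k in (0.5, 2.0, 10.0):
        scaled_sched = rf.scale_schedule(sched, k)
        scaled_cfg = rf.DepartmentConfig(
            prep_capacity_per_week=100 * k, treat_capacity_per_day=330 * k
        )
        scaled = rf.run(scaled_sched, scaled_cfg, scenario()).frame
        for c in cols:
            np.testing.assert_allclose(
                scaled[c], k * base[c], rtol=1e-9, atol=1e-9, err_msg=f"{c} k={k}"
            )


def test_more_treat_capacity_never_lengthens_ready_queue():
    rng = np.random.default_rng(7)
    sched = make_reference_schedule(2)
    low = rf.run(sched, rf.DepartmentConfig(treat_capacity_per_day=250)).frame
    for cap in (260, 300, 330):
        hi = rf.run(sched, rf.DepartmentConfig(treat_capacity_per_day=float(cap))).frame
        assert (hi["ready_to_start"] <= low["ready_to_start"] + 1e-9).all()
        low = hi


class TestOracleEquivalence:
    """The continuous engine must coincide with an independent per-patient
    event-list simulation on integer instances where both semantics agree."""

    COMPARED = ["prep_starts", "prep_completions", "treatment_starts",
                "fractions_delivered", "overtime_units", "idle_units",
                "awaiting_prep", "in_prep", "ready_to_start", "in_treatment",
                "completed"]

    def _compare(self, weekly_arrivals, fractions, prep_cap_week, treat_cap, weight, lead=8):
        weeks = len(weekly_arrivals)
        groups = [
            rf.WorkflowGroup(f"g{i}", f"g{i}", "curative", float(f),
                             np.array([row[i] for row in weekly_arrivals], dtype=float))
            for i, f in enumerate(fractions)
        ]
        sched = rf.ReferralSchedule(groups=groups, horizon_weeks=weeks)
        cfg = rf.DepartmentConfig(
            prep_capacity_per_week=float(prep_cap_week),
            treat_capacity_per_day=float(treat_cap),
            prep_lead_working_days=lead,
            first_fraction_weight=float(weight),
        )
        engine = rf.run(sched, cfg).frame
        oracle = oracle_run(weekly_arrivals, fractions, lead,
                            prep_cap_week / 5.0, treat_cap, weight)
        for col in self.COMPARED:
            np.testing.assert_allclose(
                engine[col], [d[col] for d in oracle], atol=1e-9, rtol=0,
                err_msg=col,
            )

    def test_random_instances(self):
        rng = np.random.default_rng(2024)
        for i in range(60):
            kind = i % 3
            weeks = int(rng.integers(3, 21))
            if kind == 0:  # multi-group, ample everywhere
                n_groups = int(rng.integers(1, 6))
                arrivals = rng.integers(0, 5, size=(weeks, n_groups)).tolist()
                fractions = rng.integers(1, 12, size=n_groups).tolist()
                self._compare(arrivals, fractions, 10_000, 10_000,
                              weight=int(rng.integers(1, 3)))
            elif kind == 1:  # single group, binding integer prep capacity
                arrivals = rng.integers(0, 12, size=(weeks, 1)).tolist()
                fractions = [int(rng.integers(1, 10))]
                self._compare(arrivals, fractions, prep_cap_week=5 * int(rng.integers(1, 5)),
                              treat_cap=10_000, weight=2)
            else:  # single group, binding integer treat capacity, weight 1
                arrivals = rng.integers(0, 8, size=(weeks, 1)).tolist()
                fractions = [int(rng.integers(1, 8))]
                self._compare(arrivals, fractions, prep_cap_week=10_000,
                              treat_cap=int(rng.integers(1, 15)), weight=1)
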