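"""Independent per-patient event-list simulator used as a test oracle.

Simulates individual (integer) patients with explicit Python lists and
scalar arithmetic — no shared code with the engine's vectorised
continuous-flow implementation.  Valid comparisons require instances on
which both formulations coincide: integer arrivals and either ample
capacity, a binding integer preparation capacity with a single group, or a
binding integer treatment capacity with a single group and first-fraction
weight 1 (otherwise the continuous engine legitimately starts fractional
patients).
"""

from dataclasses import dataclass


@dataclass
class _Patient:
    group: int
    remaining: int  # fractions still to receive (including today's, once ongoing)


def oracle_run(
    weekly_arrivals,  # list over weeks of per-group integer counts
    fractions,  # per-group integer fraction count
    prep_lead_days: int,
    prep_cap: float,
    treat_cap: float,
    weight: int,
    days_per_week: int = 5,
):
    """Returns a list of per-day dicts of totals (flows and stocks)."""
    n_weeks = len(weekly_arrivals)
    awaiting: list[int] = []  # group indices, FIFO
    in_prep: list[tuple[int, int]] = []  # (exit_day, group)
    ready: list[int] = []  # group indices, FIFO by completion then group order
    ongoing: list[_Patient] = []
    completed = 0
    out = []

    for day in range(n_weeks * days_per_week):
        week, weekday = divmod(day, days_per_week)
        if weekday == 0:
            for g, count in enumerate(weekly_arrivals[week]):
                awaiting.extend([g] * int(count))

        # preparation: capacity limits entries; fixed pipeline delay
        n_prep = min(len(awaiting), int(prep_cap))
        for _ in range(n_prep):
            in_prep.append((day + prep_lead_days, awaiting.pop(0)))
        exits = [g for (d, g) in in_prep if d == day]
        in_prep = [(d, g) for (d, g) in in_prep if d != day]
        ready.extend(exits)

        # treatment: yesterday's finishers leave, ongoing always served
        finished = [p for p in ongoing if p.remaining == 0]
        completed += len(finished)
        ongoing = [p for p in ongoing if p.remaining > 0]
        demand = len(ongoing)
        for p in ongoing:
            p.remaining -= 1
        overtime = max(0, demand - treat_cap)
        residual = max(0.0, treat_cap - demand)
        n_starts = min(len(ready), int(residual // weight))
        started = [ready.pop(0) for _ in range(n_starts)]
        for g in started:
            ongoing.append(_Patient(group=g, remaining=fractions[g] - 1))
        delivered = demand + weight * n_starts
        idle = max(0.0, treat_cap - demand - weight * n_starts)

        out.append(
            {
                "prep_starts": n_prep,
                "prep_completions": len(exits),
                "treatment_starts": n_starts,
                "fractions_delivered": delivered,
                "overtime_units": overtime,
                "idle_units": idle,
                "awaiting_prep": len(awaiting),
                "in_prep": len(in_prep),
                "ready_to_start": len(ready),
                "in_treatment": len(ongoing),
                "completed": completed,
            }
        )
    return out
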