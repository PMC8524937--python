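"""Seeded synthetic booking extracts.

Real referral extracts from oncology information systems are not publicly
shareable, so this module generates extracts with the same statistical
structure: weekly Poisson referral arrivals, a roughly 65/35
curative/palliative intent split, a long-tailed (Zipf-like) diagnosis-group
size distribution over ~128 raw diagnosis-by-intent workflows whose 80/20
Pareto aggregation lands near 21 groups, and intent-dependent fraction
counts.  Optionally injects exact-duplicate and non-logical rows at stated
rates so the cleaning stage can be exercised end to end.

Everything is reproducible from the seed alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .referrals import BookingRecord, ReferralSchedule, WorkflowGroup

__all__ = [
    "SynthParams",
    "generate_bookings",
    "generate_constant_schedule",
    "write_bookings_csv",
    "BOOKINGS_EPOCH_MONDAY",
]

#: Monday of the first referral week in generated CSVs (an arbitrary but
#: fixed epoch so week indices round-trip through ISO dates).
BOOKINGS_EPOCH_MONDAY = np.datetime64("2015-01-05")


@dataclass
class SynthParams:
    """Generator settings; the defaults define the reference study conditions.

    mean_weekly_referrals defaults to 3209/70 (≈45.8), a department-scale
    inflow of referred patients over a 70-week horizon.  ``tail_exponent`` is
    the Zipf decay of diagnosis-group sizes; with 128 raw groups it is set so
    that the 80/20 cut yields on the order of 20 workflow groups.
    ``inject_duplicates`` / ``inject_invalid`` append round(rate * n) exact
    duplicates / non-logical rows to the clean body of n records.
    """

    seed: int = 0
    weeks: int = 70
    mean_weekly_referrals: float = 3209 / 70
    curative_share: float = 0.65
    n_raw_groups: int = 128
    tail_exponent: float = 1.4
    curative_fraction_range: tuple[int, int] = (15, 35)
    palliative_fraction_range: tuple[int, int] = (1, 10)
    inject_duplicates: float = 0.0
    inject_invalid: float = 0.0
    seasonal_amplitude: float = 0.0  # optional sinusoidal modulation, off by default

    def __post_init__(self) -> None:
        if self.weeks < 1:
            raise ValueError("weeks must be >= 1")
        if not 0 <= self.curative_share <= 1:
            raise ValueError("curative_share must be in [0, 1]")
        if self.n_raw_groups < 1:
            raise ValueError("n_raw_groups must be >= 1")
        if self.mean_weekly_referrals <= 0:
            raise ValueError("mean_weekly_referrals must be > 0")
        if self.tail_exponent <= 0:
            raise ValueError("tail_exponent must be > 0")
        for name in ("inject_duplicates", "inject_invalid"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 <= self.seasonal_amplitude < 1:
            raise ValueError("seasonal_amplitude must be in [0, 1)")


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** -exponent
    return w / w.sum()


def generate_bookings(params: SynthParams) -> list[BookingRecord]:
    """Draw a synthetic booking extract; byte-identical for a fixed seed.

    Weekly referral counts are Poisson(mean_weekly_referrals), each referral
    gets an intent (Bernoulli curative_share), a diagnosis group (Zipf-like
    over the intent's share of n_raw_groups) and a per-intent uniform integer
    fraction count.  Injected duplicates are exact copies of existing rows
    appended at the end; injected invalid rows cycle through the non-logical
    kinds (zero fractions, unknown intent, missing referral week).
    """
    rng = np.random.default_rng(params.seed)

    n_cur = min(max(int(round(params.n_raw_groups * params.curative_share)), 1),
                params.n_raw_groups - 1) if params.n_raw_groups > 1 else 1
    n_pal = params.n_raw_groups - n_cur
    group_pool = {
        "curative": ([f"dx_cur_{k:03d}" for k in range(1, n_cur + 1)],
                     _zipf_weights(n_cur, params.tail_exponent)),
    }
    if n_pal > 0:
        group_pool["palliative"] = (
            [f"dx_pal_{k:03d}" for k in range(1, n_pal + 1)],
            _zipf_weights(n_pal, params.tail_exponent),
        )
    frac_range = {
        "curative": params.curative_fraction_range,
        "palliative": params.palliative_fraction_range,
    }

    records: list[BookingRecord] = []
    counter = 0
    for week in range(1, params.weeks + 1):
        mean = params.mean_weekly_referrals
        if params.seasonal_amplitude:
            mean *= 1.0 + params.seasonal_amplitude * math.sin(
                2 * math.pi * (week - 1) / 52.0
            )
        n_week = rng.poisson(mean)
        for _ in range(n_week):
            counter += 1
            curative = rng.random() < params.curative_share
            intent = "curative" if (curative or "palliative" not in group_pool) else "palliative"
            labels, weights = group_pool[intent]
            diagnosis = labels[rng.choice(len(labels), p=weights)]
            lo, hi = frac_range[intent]
            records.append(
                BookingRecord(
                    patient_id=f"P{counter:06d}",
                    course_id=f"C{counter:06d}",
                    referral_week=week,
                    diagnosis=diagnosis,
                    intent=intent,
                    n_fractions=int(rng.integers(lo, hi + 1)),
                )
            )

    n_clean = len(records)
    n_dup = int(round(params.inject_duplicates * n_clean))
    if n_dup and n_clean:
        picks = rng.choice(n_clean, size=n_dup, replace=False)
        for i in sorted(picks):
            src = records[i]
            records.append(BookingRecord(**{
                f: getattr(src, f)
                for f in ("patient_id", "course_id", "referral_week",
                          "diagnosis", "intent", "n_fractions")
            }))

    n_inv = int(round(params.inject_invalid * n_clean))
    kinds = ("fractions", "intent", "week")
    for j in range(n_inv):
        counter += 1
        kind = kinds[j % len(kinds)]
        records.append(
            BookingRecord(
                patient_id=f"P{counter:06d}",
                course_id=f"C{counter:06d}",
                referral_week=None if kind == "week" else int(rng.integers(1, params.weeks + 1)),
                diagnosis="dx_invalid",
                intent="unknown" if kind == "intent" else "palliative",
                n_fractions=0 if kind == "fractions" else 1,
            )
        )
    return records


def generate_constant_schedule(
    rate: float, weeks: int, n_fractions: float
) -> ReferralSchedule:
    """Deterministic single-group schedule with a constant weekly inflow."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if weeks < 1:
        raise ValueError("weeks must be >= 1")
    group = WorkflowGroup(
        group_id="constant|all",
        diagnosis="constant",
        intent="curative",
        n_fractions=float(n_fractions),
        weekly_counts=np.full(weeks, float(rate)),
    )
    return ReferralSchedule(groups=[group], horizon_weeks=weeks)


def write_bookings_csv(
    records: list[BookingRecord], path: str | Path, seed: int | None = None
) -> None:
    """Write records in the bookings CSV dialect ``load_bookings`` reads.

    Week indices are materialised as ISO dates (Monday of each week from a
    fixed epoch); the seed, when given, is recorded in a leading comment line.
    """
    lines = []
    if seed is not None:
        lines.append(f"# seed={seed}")
    lines.append(",".join(
        ("patient_id", "course_id", "referral_date", "diagnosis", "intent", "n_fractions")
    ))
    for rec in records:
        if rec.referral_week is None:
            date = ""
        else:
            date = str(BOOKINGS_EPOCH_MONDAY + np.timedelta64(7 * (rec.referral_week - 1), "D"))
        lines.append(
            f"{rec.patient_id},{rec.course_id},{date},{rec.diagnosis},"
            f"{rec.intent},{rec.n_fractions}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
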