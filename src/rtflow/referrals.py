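"""Booking-record ingestion and case-mix aggregation.

A radiotherapy department's booking extract has one row per scheduled
treatment course (referral date, diagnosis, treatment intent, number of
fractions).  This module turns such an extract into the simulation engine's
input: records are cleaned, grouped by diagnosis and intent, reduced with the
80/20 Pareto rule to the high-volume workflow groups (the long tail is pooled
per intent), batched into weekly referral counts, and optionally scaled to a
target yearly volume.

Counts stay real-valued throughout: the downstream engine is a continuous
(stock-and-flow) model and integer rounding would distort low-volume groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INTENTS",
    "BookingRecord",
    "WorkflowGroup",
    "ReferralSchedule",
    "PreprocessParams",
    "CleaningReport",
    "RowError",
    "load_bookings",
    "clean_bookings",
    "pareto_aggregate",
    "build_schedule",
    "scale_schedule",
    "compute_scaling_factor",
]

#: The two treatment intents the case mix is split by.
INTENTS = ("curative", "palliative")

#: Canonical column names of the bookings CSV dialect.
BOOKING_COLUMNS = (
    "patient_id",
    "course_id",
    "referral_date",
    "diagnosis",
    "intent",
    "n_fractions",
)


@dataclass(slots=True)
class BookingRecord:
    """One scheduled treatment course from a booking extract.

    ``referral_week`` is a 1-based ISO-week index relative to the earliest
    referral in the extract; ``None`` marks a record whose referral date was
    missing (removed later as non-logical).  Validity (positive fraction
    count, known intent) is *not* enforced here — raw extracts contain
    non-logical rows and :func:`clean_bookings` is the place they are removed
    and reported.
    """

    patient_id: str
    course_id: str
    referral_week: int | None
    diagnosis: str
    intent: str
    n_fractions: int


@dataclass
class WorkflowGroup:
    """An aggregated diagnosis-by-intent class sharing a fraction schedule.

    ``n_fractions`` is the group-representative fraction count; for pooled
    tail groups it is the patient-weighted mean of the pooled records and may
    be fractional.  ``weekly_counts[w]`` is the (real-valued) number of
    referrals in week ``w + 1``.
    """

    group_id: str
    diagnosis: str
    intent: str
    n_fractions: float
    weekly_counts: np.ndarray

    def __post_init__(self) -> None:
        self.weekly_counts = np.asarray(self.weekly_counts, dtype=float)
        if self.n_fractions <= 0:
            raise ValueError(f"group {self.group_id}: n_fractions must be > 0")
        if (self.weekly_counts < 0).any():
            raise ValueError(f"group {self.group_id}: negative weekly count")

    @property
    def total_patients(self) -> float:
        return float(self.weekly_counts.sum())


@dataclass
class ReferralSchedule:
    """Weekly-batched referral counts per workflow group over a horizon."""

    groups: list[WorkflowGroup]
    horizon_weeks: int
    scaling_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.horizon_weeks < 1:
            raise ValueError("horizon_weeks must be >= 1")
        for g in self.groups:
            if len(g.weekly_counts) != self.horizon_weeks:
                raise ValueError(
                    f"group {g.group_id}: weekly_counts length "
                    f"{len(g.weekly_counts)} != horizon {self.horizon_weeks}"
                )

    @property
    def total_patients(self) -> float:
        return float(sum(g.total_patients for g in self.groups))

    @property
    def group_ids(self) -> list[str]:
        return [g.group_id for g in self.groups]

    def arrivals_matrix(self) -> np.ndarray:
        """(horizon_weeks, n_groups) matrix of weekly referral counts."""
        if not self.groups:
            return np.zeros((self.horizon_weeks, 0))
        return np.column_stack([g.weekly_counts for g in self.groups])

    def fraction_counts(self) -> np.ndarray:
        return np.array([g.n_fractions for g in self.groups], dtype=float)

    # -- long-format CSV round trip -------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for week, count in enumerate(g.weekly_counts, start=1):
                rows.append(
                    (g.group_id, g.diagnosis, g.intent, g.n_fractions, week, count)
                )
        return pd.DataFrame(
            rows,
            columns=["group_id", "diagnosis", "intent", "n_fractions", "week", "count"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scaling_factor: float = 1.0) -> "ReferralSchedule":
        horizon = int(frame["week"].max()) if len(frame) else 1
        groups = []
        for gid, sub in frame.groupby("group_id", sort=True):
            counts = np.zeros(horizon)
            counts[sub["week"].to_numpy(dtype=int) - 1] = sub["count"].to_numpy(dtype=float)
            groups.append(
                WorkflowGroup(
                    group_id=str(gid),
                    diagnosis=str(sub["diagnosis"].iloc[0]),
                    intent=str(sub["intent"].iloc[0]),
                    n_fractions=float(sub["n_fractions"].iloc[0]),
                    weekly_counts=counts,
                )
            )
        return cls(groups=groups, horizon_weeks=horizon, scaling_factor=scaling_factor)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ReferralSchedule":
        return cls.from_frame(pd.read_csv(path, comment="#"))


@dataclass
class PreprocessParams:
    """Cleaning and Pareto-aggregation settings.

    ``pareto_share`` is the cumulative patient share at which the descending
    group-size cut stops (0.8 implements the 80/20 rule); the remainder is
    pooled into one "other" group per intent when ``pool_by_intent`` is set.
    """

    pareto_share: float = 0.8
    pool_by_intent: bool = True
    dedupe_keys: tuple[str, ...] = ("patient_id", "course_id")

    def __post_init__(self) -> None:
        if not 0 < self.pareto_share <= 1:
            raise ValueError("pareto_share must be in (0, 1]")


@dataclass
class RowError:
    """A row-level ingestion problem (1-based row number within the data)."""

    row: int
    message: str


@dataclass
class CleaningReport:
    input_rows: int
    kept: int
    removed_by_reason: dict[str, int] = field(default_factory=dict)
    row_numbers: dict[str, list[int]] = field(default_factory=dict)

    @property
    def removed(self) -> int:
        return sum(self.removed_by_reason.values())

    def to_dict(self) -> dict:
        return {
            "input_rows": self.input_rows,
            "kept": self.kept,
            "removed_by_reason": dict(self.removed_by_reason),
            "row_numbers": {k: list(v) for k, v in self.row_numbers.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _iso_week_monday(ts: pd.Timestamp) -> pd.Timestamp:
    return (ts - pd.Timedelta(days=ts.weekday())).normalize()


def load_bookings(
    path: str | Path,
    dialect: dict[str, str] | None = None,
) -> tuple[list[BookingRecord], list[RowError]]:
    """Read a bookings CSV into records plus a list of row-level errors.

    ``dialect`` maps canonical column names (``patient_id``, ``course_id``,
    ``referral_date``, ``diagnosis``, ``intent``, ``n_fractions``) to the
    file's actual column names.  A missing column raises ``ValueError``
    naming it; unparseable dates and non-positive or non-integer fraction
    counts are collected per row (1-based data row numbers) instead of
    raising.  Referral dates become 1-based week indices relative to the ISO
    week of the earliest parseable referral.
    """
    colmap = {c: c for c in BOOKING_COLUMNS}
    if dialect:
        colmap.update(dialect)
    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    for canonical, actual in colmap.items():
        if actual not in frame.columns:
            raise ValueError(f"bookings file is missing required column {actual!r}")
    if frame.empty:
        return [], []

    dates = pd.to_datetime(frame[colmap["referral_date"]], errors="coerce", format="mixed")
    valid_dates = dates.dropna()
    origin = _iso_week_monday(valid_dates.min()) if len(valid_dates) else None

    records: list[BookingRecord] = []
    errors: list[RowError] = []
    for i in range(len(frame)):
        rownum = i + 1
        raw_frac = frame[colmap["n_fractions"]].iloc[i].strip()
        try:
            n_fractions = int(float(raw_frac))
            if float(raw_frac) != n_fractions:
                raise ValueError
        except ValueError:
            errors.append(RowError(rownum, f"unparseable n_fractions {raw_frac!r}"))
            continue
        if n_fractions < 1:
            errors.append(RowError(rownum, f"non-positive n_fractions {n_fractions}"))
            continue
        date = dates.iloc[i]
        raw_date = frame[colmap["referral_date"]].iloc[i].strip()
        if pd.isna(date):
            if raw_date:
                errors.append(RowError(rownum, f"unparseable referral_date {raw_date!r}"))
                continue
            week = None  # genuinely missing; removed later as non-logical
        else:
            week = int((_iso_week_monday(date) - origin).days // 7) + 1
        records.append(
            BookingRecord(
                patient_id=frame[colmap["patient_id"]].iloc[i],
                course_id=frame[colmap["course_id"]].iloc[i],
                referral_week=week,
                diagnosis=frame[colmap["diagnosis"]].iloc[i],
                intent=frame[colmap["intent"]].iloc[i].strip().lower(),
                n_fractions=n_fractions,
            )
        )
    return records, errors


def clean_bookings(
    records: Sequence[BookingRecord],
    params: PreprocessParams | None = None,
) -> tuple[list[BookingRecord], CleaningReport]:
    """Remove duplicate and non-logical bookings; report every removal.

    Non-logical rules (checked first, in order): fraction count < 1, missing
    or non-positive referral week, intent outside {curative, palliative}.
    Exact duplicates on ``params.dedupe_keys`` are then removed keeping the
    first occurrence in input order.  Cleaning is total: kept + removed
    always equals the input count.
    """
    params = params or PreprocessParams()
    kept: list[BookingRecord] = []
    report = CleaningReport(input_rows=len(records), kept=0)
    seen: set[tuple] = set()

    def remove(rownum: int, reason: str) -> None:
        report.removed_by_reason[reason] = report.removed_by_reason.get(reason, 0) + 1
        report.row_numbers.setdefault(reason, []).append(rownum)

    for i, rec in enumerate(records, start=1):
        if rec.n_fractions is None or rec.n_fractions < 1:
            remove(i, "non-logical: fractions")
            continue
        if rec.referral_week is None or rec.referral_week < 1:
            remove(i, "non-logical: week")
            continue
        if rec.intent not in INTENTS:
            remove(i, "non-logical: intent")
            continue
        key = tuple(getattr(rec, k) for k in params.dedupe_keys)
        if key in seen:
            remove(i, "duplicate")
            continue
        seen.add(key)
        kept.append(rec)
    report.kept = len(kept)
    return kept, report


def _group_label(diagnosis: str, intent: str) -> str:
    return f"{diagnosis}|{intent}"


def pareto_aggregate(
    records: Sequence[BookingRecord],
    params: PreprocessParams | None = None,
    horizon_weeks: int | None = None,
) -> list[WorkflowGroup]:
    """Group cleaned records by (diagnosis, intent) and apply the 80/20 cut.

    Groups are sorted by patient count descending (ties broken
    lexicographically by group label) and retained until the cumulative
    patient share first reaches ``pareto_share``; the remaining records are
    pooled into one "other" group per intent whose fraction count is the
    patient-weighted mean of its members.  Total patients are conserved
    exactly.  Empty input yields an empty list.
    """
    params = params or PreprocessParams()
    if not records:
        return []
    if horizon_weeks is None:
        horizon_weeks = max(r.referral_week for r in records)

    by_key: dict[tuple[str, str], list[BookingRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.diagnosis, rec.intent), []).append(rec)

    order = sorted(
        by_key, key=lambda k: (-len(by_key[k]), _group_label(*k))
    )
    total = len(records)
    threshold = params.pareto_share * total
    cumulative = 0
    kept_keys: list[tuple[str, str]] = []
    tail_keys: list[tuple[str, str]] = []
    for key in order:
        if cumulative >= threshold:
            tail_keys.append(key)
        else:
            kept_keys.append(key)
            cumulative += len(by_key[key])

    def counts_of(members: Iterable[BookingRecord]) -> np.ndarray:
        counts = np.zeros(horizon_weeks)
        for rec in members:
            counts[rec.referral_week - 1] += 1.0
        return counts

    groups: list[WorkflowGroup] = []
    for diagnosis, intent in kept_keys:
        members = by_key[(diagnosis, intent)]
        groups.append(
            WorkflowGroup(
                group_id=_group_label(diagnosis, intent),
                diagnosis=diagnosis,
                intent=intent,
                n_fractions=float(np.mean([r.n_fractions for r in members])),
                weekly_counts=counts_of(members),
            )
        )

    if tail_keys:
        pools: dict[str, list[BookingRecord]] = {}
        for key in tail_keys:
            intent = key[1] if params.pool_by_intent else "all"
            pools.setdefault(intent, []).extend(by_key[key])
        for intent in sorted(pools):
            members = pools[intent]
            groups.append(
                WorkflowGroup(
                    group_id=_group_label("other", intent),
                    diagnosis="other",
                    intent=intent,
                    n_fractions=float(np.mean([r.n_fractions for r in members])),
                    weekly_counts=counts_of(members),
                )
            )
    return groups


def build_schedule(
    records: Sequence[BookingRecord],
    params: PreprocessParams | None = None,
    horizon_weeks: int | None = None,
) -> ReferralSchedule:
    """Convenience: Pareto-aggregate cleaned records into a ReferralSchedule."""
    if horizon_weeks is None and records:
        horizon_weeks = max(r.referral_week for r in records)
    groups = pareto_aggregate(records, params, horizon_weeks)
    return ReferralSchedule(groups=groups, horizon_weeks=horizon_weeks or 1)


def scale_schedule(schedule: ReferralSchedule, factor: float) -> ReferralSchedule:
    """Multiply every weekly count by ``factor`` (counts stay real-valued)."""
    if factor <= 0:
        raise ValueError("scaling factor must be > 0")
    groups = [
        replace(g, weekly_counts=g.weekly_counts * factor) for g in schedule.groups
    ]
    return ReferralSchedule(
        groups=groups,
        horizon_weeks=schedule.horizon_weeks,
        scaling_factor=schedule.scaling_factor * factor,
    )


def compute_scaling_factor(
    historical_total: float,
    historical_weeks: float,
    target_total: float,
    target_weeks: float,
) -> float:
    """Ratio of target weekly volume to historical weekly volume.

    E.g. scaling a 3666-courses / 70-weeks extract to a 4610-courses /
    53-weeks year gives (4610/53)/(3666/70) ≈ 1.66, used as 1.7 after
    one-decimal rounding.
    """
    args = (historical_total, historical_weeks, target_total, target_weeks)
    if any(a <= 0 for a in args):
        raise ValueError("all scaling-factor arguments must be > 0")
    return (target_total / target_weeks) / (historical_total / historical_weeks)
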