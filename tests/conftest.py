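import numpy as np
import pytest

import rtflow as rf


def make_reference_schedule(seed: int) -> rf.ReferralSchedule:
    """Department-scale referral schedule: default synthetic extract,
    cleaned, Pareto-aggregated and scaled by the 2020 volume factor 1.7."""
    records = rf.generate_bookings(rf.SynthParams(seed=seed))
    kept, _ = rf.clean_bookings(records)
    return rf.scale_schedule(rf.build_schedule(kept, horizon_weeks=70), 1.7)


@pytest.fixture(scope="session")
def dept() -> rf.DepartmentConfig:
    return rf.DepartmentConfig()


@pytest.fixture(scope="session")
def reference_schedule() -> rf.ReferralSchedule:
    return make_reference_schedule(0)


@pytest.fixture()
def bookings_csv(tmp_path):
    """Three well-formed rows whose referral dates fall in ISO weeks 1, 1, 2."""
    path = tmp_path / "bookings.csv"
    path.write_text(
        "patient_id,course_id,referral_date,diagnosis,intent,n_fractions\n"
        "P1,C1,2021-01-04,breast,curative,25\n"
        "P2,C2,2021-01-08,lung,palliative,5\n"
        "P3,C3,2021-01-12,breast,curative,25\n"
    )
    return path


def records_fixture() -> list[rf.BookingRecord]:
    """10 rows: 7 valid, 2 duplicates of valid rows, 1 invalid intent."""
    base = [
        rf.BookingRecord(f"P{i}", f"C{i}", 1 + i % 3, d, intent, nf)
        for i, (d, intent, nf) in enumerate(
            [
                ("breast", "curative", 25),
                ("lung", "curative", 30),
                ("prostate", "curative", 20),
                ("breast", "palliative", 5),
                ("lung", "palliative", 3),
                ("bone", "palliative", 1),
                ("brain", "curative", 15),
            ]
        )
    ]
    dup1 = rf.BookingRecord("P0", "C0", 1, "breast", "curative", 25)
    dup2 = rf.BookingRecord("P3", "C3", 2, "breast", "palliative", 5)
    bad = rf.BookingRecord("P9", "C9", 2, "skin", "unknown", 4)
    return base + [dup1, dup2, bad]
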