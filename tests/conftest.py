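"""Shared fixtures and the day-grid PDC oracle used across the suite."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import settings

from adhertraj.pdc import DispensingRecord

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=60)
settings.load_profile("suite")

WINDOW_START = date(2022, 1, 1)


def day_grid_oracle(records, window_start, window_days):
    """Independent PDC ground truth: simulate a pill stockpile day by day.

    Each morning any fill dated that day is added to the stockpile; a day is
    covered when at least one day of supply is on hand, which is then
    consumed.  This realises the banked-supply convention without interval
    arithmetic.
    """
    covered = np.zeros(window_days, dtype=bool)
    if not records:
        return covered
    fills: dict[int, int] = {}
    for r in records:
        off = (r.fill_date - window_start).days
        fills[off] = fills.get(off, 0) + r.days_supply
    bank = 0
    for day in range(min(fills), window_days):
        bank += fills.get(day, 0)
        if bank > 0:
            bank -= 1
            if day >= 0:
                covered[day] = True
    return covered


def make_records(offsets_supplies, patient_id="P1", window_start=WINDOW_START):
    """Build records from (day-offset, days-supply) pairs."""
    return [
        DispensingRecord(patient_id, window_start + timedelta(days=int(off)), int(sup))
        for off, sup in offsets_supplies
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220101)
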