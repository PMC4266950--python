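"""Shared fixtures and independent oracles for the test suite."""

from datetime import date, timedelta

import numpy as np
import pytest

from refillkit import DispensingEvent, fixture_bundle

START = date(2009, 1, 1)


@pytest.fixture
def start_date():
    return START


@pytest.fixture
def worked_fixture():
    """The four hand-built patients used throughout the suite."""
    return fixture_bundle()


def event(day: int, supply: int = 30, pid: str = "p") -> DispensingEvent:
    return DispensingEvent(pid, START + timedelta(days=day), supply)


def brute_force_covered_days(events, window_start, window_end) -> int:
    """Independent day-by-day possession oracle.

    Walks calendar dates (not offsets) with a medication pool: the pool is
    seeded with the leftover of the latest collection before the window,
    topped up on each collection date, and drained one day at a time.
    """
    pool = 0
    prior = [e for e in events if e.dispense_date < window_start]
    if prior:
        last_date = max(e.dispense_date for e in prior)
        supplied = sum(e.days_supplied for e in prior if e.dispense_date == last_date)
        pool = max(0, (last_date - window_start).days + supplied)
    covered = 0
    day = window_start
    while day < window_end:
        for e in events:
            if e.dispense_date == day:
                pool += e.days_supplied
        if pool > 0:
            covered += 1
            pool -= 1
        day += timedelta(days=1)
    return covered


def random_history(rng: np.random.Generator, pid: str = "p"):
    """A random dispensing history: sorted events over roughly a year."""
    n = int(rng.integers(0, 15))
    days = np.sort(rng.choice(np.arange(-60, 400), size=n, replace=False)) if n else []
    return [
        DispensingEvent(pid, START + timedelta(days=int(d)), int(rng.integers(1, 121)))
        for d in days
    ]
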