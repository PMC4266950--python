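"""Pharmacy-refill adherence calculators.

Four estimators of adherence from dispensing records, all expressed as a
percentage and truncated at 100%:

``interval_gap``
    Proportion of days covered (PDC) with forward carryover: a day-by-day
    possession simulation over the window before a viral load, seeded with
    the unused supply from the last collection before the window.  Surplus
    carries forward without cap, but never covers days retroactively —
    this asymmetry is what lets the method see gaps that supply-averaging
    methods smooth over.

``interval_average``
    Medication-possession-ratio (MPR) style arithmetic: days dispensed in
    the window, plus carry-in from the last prior collection, minus the
    unused tail of the last in-window collection, over window length.

``interval_crude``
    Refill count (or supply-weighted refill count) per month of window.

``overall``
    Total days dispensed since second-line initiation over total days on
    second-line therapy before the viral load of interest.

Windows are half-open ``[start, end)`` where ``end`` is the anchoring VL
date: adherence is measured strictly before the VL, and the VL day itself
is excluded.  By default the window start is ``end`` minus a whole number
of calendar months (day-of-month preserved, clamped to month end); a fixed
mean month length can be used instead via ``month_length_days``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np

from .io import DispensingEvent, add_months, days_between

METHODS = ("interval_gap", "interval_average", "interval_crude")
OVERALL = "overall"
DEFAULT_DURATIONS = tuple(range(3, 13))  # months

#: key used for the long-term result in adherence grids
OVERALL_KEY = (OVERALL, None)


@dataclass(frozen=True)
class AdherenceInterval:
    """A (patient, VL-date, duration) assessment window, half-open [start, end)."""

    patient_id: str
    end_date: date
    duration_months: int
    start_date: date
    length_days: int

    def __post_init__(self) -> None:
        if self.start_date >= self.end_date:
            raise ValueError("interval start must precede end")
        if self.length_days != days_between(self.start_date, self.end_date):
            raise ValueError("length_days inconsistent with start/end dates")


@dataclass(frozen=True)
class CoverageProfile:
    """Per-day possession over an interval."""

    interval: AdherenceInterval
    covered: np.ndarray  # bool, one entry per day of the interval
    carry_in_days: int
    covered_day_count: int


@dataclass(frozen=True)
class AdherenceResult:
    method: str
    raw_percent: float
    percent: float  # truncated to [0, 100]


def make_interval(
    patient_id: str,
    end_date: date,
    duration_months: int,
    month_length_days: float | None = None,
) -> AdherenceInterval:
    """Build the assessment window ending (exclusively) at ``end_date``.

    ``month_length_days=None`` (default) subtracts calendar months;
    a float (e.g. 30.4375) subtracts ``round(duration * month_length_days)``
    days instead.
    """
    if month_length_days is None:
        start = add_months(end_date, -duration_months)
    else:
        start = end_date - timedelta(days=round(duration_months * month_length_days))
    return AdherenceInterval(
        patient_id=patient_id,
        end_date=end_date,
        duration_months=duration_months,
        start_date=start,
        length_days=days_between(start, end_date),
    )


def _result(method: str, raw: float) -> AdherenceResult:
    raw = max(0.0, raw)
    return AdherenceResult(method=method, raw_percent=raw, percent=min(raw, 100.0))


def carry_in(events: Sequence[DispensingEvent], interval: AdherenceInterval) -> int:
    """Days of supply accrued from the last collection strictly before the window.

    Only the single most recent prior collection date counts (same-day
    dispensings are pooled); older unexhausted stockpiles are ignored.
    Zero when there is no prior event or its supply ran out before the
    window started.
    """
    last_date = None
    supplied = 0
    for ev in events:
        if ev.dispense_date >= interval.start_date:
            break
        if ev.dispense_date != last_date:
            last_date, supplied = ev.dispense_date, 0
        supplied += ev.days_supplied
    if last_date is None:
        return 0
    return max(0, supplied - days_between(last_date, interval.start_date))


def daily_coverage(
    events: Sequence[DispensingEvent], interval: AdherenceInterval
) -> CoverageProfile:
    """Forward possession simulation over the window.

    The supply balance starts at :func:`carry_in`.  Each day, supply
    dispensed that day is added first; if the balance is at least one day
    the day is covered and one day of supply is consumed.  Surplus carries
    forward without cap; supply never covers days before its dispense date.
    """
    n = interval.length_days
    if n <= 0:
        raise ValueError("zero-length interval")
    supply_on: dict[int, int] = {}
    for ev in events:
        off = days_between(interval.start_date, ev.dispense_date)
        if 0 <= off < n:
            supply_on[off] = supply_on.get(off, 0) + ev.days_supplied
    carry = carry_in(events, interval)
    balance = carry
    covered = np.zeros(n, dtype=bool)
    for d in range(n):
        balance += supply_on.get(d, 0)
        if balance >= 1:
            covered[d] = True
            balance -= 1
    return CoverageProfile(
        interval=interval,
        covered=covered,
        carry_in_days=carry,
        covered_day_count=int(covered.sum()),
    )


def interval_gap(
    events: Sequence[DispensingEvent], interval: AdherenceInterval
) -> AdherenceResult:
    """Covered days over window days (PDC with carryover); see module docs."""
    profile = daily_coverage(events, interval)
    raw = 100.0 * profile.covered_day_count / interval.length_days
    return _result("interval_gap", raw)


def _events_in(events, interval):
    return [
        ev for ev in events
        if interval.start_date <= ev.dispense_date < interval.end_date
    ]


def interval_average(
    events: Sequence[DispensingEvent], interval: AdherenceInterval
) -> AdherenceResult:
    """MPR-style supply arithmetic with carry-in and carry-out corrections.

    numerator = days dispensed in-window + carry-in − unused tail of the
    last in-window collection; negative numerators clamp to zero.
    """
    in_window = _events_in(events, interval)
    dispensed = sum(ev.days_supplied for ev in in_window)
    unused = 0
    if in_window:
        last_date = in_window[-1].dispense_date
        last_supplied = sum(
            ev.days_supplied for ev in in_window if ev.dispense_date == last_date
        )
        unused = max(0, last_supplied - days_between(last_date, interval.end_date))
    numerator = dispensed + carry_in(events, interval) - unused
    raw = 100.0 * numerator / interval.length_days
    return _result("interval_average", raw)


def interval_crude(
    events: Sequence[DispensingEvent],
    interval: AdherenceInterval,
    mode: str = "supply_weighted",
) -> AdherenceResult:
    """Refills per month of window.

    ``supply_weighted`` (default) counts each collection as
    days_supplied/30 refills so 60/90-day supplies are not undercounted;
    ``event_count`` is the literal refill count.
    """
    if mode not in ("supply_weighted", "event_count"):
        raise ValueError(f"unknown interval_crude mode {mode!r}")
    in_window = _events_in(events, interval)
    if mode == "event_count":
        numerator = float(len(in_window))
    else:
        numerator = sum(ev.days_supplied for ev in in_window) / 30.0
    raw = 100.0 * numerator / interval.duration_months
    return _result("interval_crude", raw)


def overall_adherence(
    events: Sequence[DispensingEvent], second_line_start: date, vl_date: date
) -> AdherenceResult:
    """Total days dispensed since second-line start over total days on therapy."""
    if vl_date <= second_line_start:
        raise ValueError("vl_date must be after second_line_start")
    total = sum(
        ev.days_supplied
        for ev in events
        if second_line_start <= ev.dispense_date < vl_date
    )
    raw = 100.0 * total / days_between(second_line_start, vl_date)
    return _result(OVERALL, raw)


def adherence_grid(
    events: Sequence[DispensingEvent],
    second_line_start: date,
    vl_date: date,
    durations: Iterable[int] = DEFAULT_DURATIONS,
    methods: Iterable[str] = METHODS,
    month_length_days: float | None = None,
    crude_mode: str = "supply_weighted",
) -> dict[tuple[str, int | None], AdherenceResult]:
    """All (method, duration) adherence results anchored at one VL, plus overall.

    Keys are ``(method, duration_months)``; the long-term result is under
    ``OVERALL_KEY`` = ``("overall", None)``.
    """
    durations = list(durations)
    if any(d not in DEFAULT_DURATIONS for d in durations):
        raise ValueError("durations must lie in 3..12 months")
    patient_id = events[0].patient_id if events else ""
    grid: dict[tuple[str, int | None], AdherenceResult] = {}
    for d in durations:
        interval = make_interval(patient_id, vl_date, d, month_length_days)
        for m in methods:
            if m == "interval_gap":
                grid[(m, d)] = interval_gap(events, interval)
            elif m == "interval_average":
                grid[(m, d)] = interval_average(events, interval)
            elif m == "interval_crude":
                grid[(m, d)] = interval_crude(events, interval, mode=crude_mode)
            else:
                raise ValueError(f"unknown method {m!r}")
    grid[OVERALL_KEY] = overall_adherence(events, second_line_start, vl_date)
    return grid
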