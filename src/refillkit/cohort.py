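"""Cohort filters, VL anchoring, and windowed suppression summaries.

The unit of analysis is the viral-load measurement: each qualifying VL
(drawn at least four months after second-line initiation) is joined to the
adherence results computed over the windows ending at that VL, together
with the patient's baseline covariates.

Patients are filtered in a fixed order, each counted once under the first
rule that removes them:

1. ``missing_data`` — ineligible or unusable records (age under 18 or
   missing core fields);
2. ``switch_not_for_vf`` — switched to second line for toxicity or other
   reasons rather than first-line virologic failure;
3. ``suppressed_with_zero_adherence`` — a suppressed VL despite zero
   measured adherence over the preceding four months, the signature of a
   patient collecting medication at another site;
4. ``no_vl_after_4_months`` — no VL at least four months after the switch,
   so no observation can be anchored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

import pandas as pd

from .io import CohortBundle, add_months, days_between
from .metrics import (
    DEFAULT_DURATIONS,
    METHODS,
    OVERALL_KEY,
    AdherenceResult,
    adherence_grid,
    interval_gap,
    make_interval,
)

DAYS_PER_MONTH = 365.25 / 12

EXCLUSION_RULES = (
    "missing_data",
    "switch_not_for_vf",
    "suppressed_with_zero_adherence",
    "no_vl_after_4_months",
)

WINDOW_MONTHS = (6, 12, 18, 24, 30, 36, 42, 48)
WINDOW_HALF_WIDTH = 3  # months; windows are [k-3, k+3)


def months_on_art(second_line_start: date, when: date) -> float:
    """Fractional months between second-line start and ``when``."""
    return days_between(second_line_start, when) / DAYS_PER_MONTH


def round_half_up_pct(count: int, total: int) -> int:
    """Integer percentage with ties rounded up (74.5 → 75), as tables print."""
    if total == 0:
        raise ZeroDivisionError("empty denominator")
    return int(math.floor(100.0 * count / total + 0.5))


@dataclass
class ExclusionReport:
    """Per-rule exclusion counts; each patient is counted under one rule only."""

    input_patient_count: int = 0
    missing_data: int = 0
    switch_not_for_vf: int = 0
    suppressed_with_zero_adherence: int = 0
    no_vl_after_4_months: int = 0
    excluded_patient_ids: dict[str, str] = field(default_factory=dict)

    @property
    def total_excluded(self) -> int:
        return sum(getattr(self, rule) for rule in EXCLUSION_RULES)

    @property
    def retained_patient_count(self) -> int:
        return self.input_patient_count - self.total_excluded

    def record(self, patient_id: str, rule: str) -> None:
        if rule not in EXCLUSION_RULES:
            raise ValueError(f"unknown exclusion rule {rule!r}")
        setattr(self, rule, getattr(self, rule) + 1)
        self.excluded_patient_ids[patient_id] = rule

    def as_dict(self) -> dict:
        return {
            "input_patient_count": self.input_patient_count,
            **{rule: getattr(self, rule) for rule in EXCLUSION_RULES},
            "retained_patient_count": self.retained_patient_count,
        }


@dataclass
class AnalysisObservation:
    """One qualifying VL joined to proximal adherence and baseline covariates."""

    patient_id: str
    vl_date: date
    copies_per_ml: float
    suppressed_50: bool
    suppressed_400: bool
    failure_1000: bool
    months_on_second_line: float
    time_band: str  # "first_year" | "after_first_year"
    sex: str
    age_at_switch: int
    baseline_cd4: float | None
    baseline_log10_vl: float | None
    cd4_imputed: bool = False
    log10_vl_imputed: bool = False
    adherence: dict[tuple[str, int | None], AdherenceResult] = field(default_factory=dict)

    @property
    def sqrt_cd4(self) -> float | None:
        return None if self.baseline_cd4 is None else math.sqrt(self.baseline_cd4)

    def adherence_percent(self, method: str, duration: int | None) -> float:
        key = OVERALL_KEY if method == "overall" else (method, duration)
        return self.adherence[key].percent


@dataclass(frozen=True)
class WindowSummary:
    """Suppression/failure counts among patients with a VL near month ``window_month``."""

    window_month: int
    n_in_care: int
    n_with_vl: int
    n_lt50: int
    n_lt400: int
    n_ge1000: int

    @property
    def pct_lt50(self) -> int | None:
        return None if self.n_with_vl == 0 else round_half_up_pct(self.n_lt50, self.n_with_vl)

    @property
    def pct_lt400(self) -> int | None:
        return None if self.n_with_vl == 0 else round_half_up_pct(self.n_lt400, self.n_with_vl)

    @property
    def pct_ge1000(self) -> int | None:
        return None if self.n_with_vl == 0 else round_half_up_pct(self.n_ge1000, self.n_with_vl)


def apply_inclusion(bundle: CohortBundle) -> tuple[CohortBundle, ExclusionReport]:
    """Retain adults (18+) who switched to second line for first-line VF."""
    report = ExclusionReport(input_patient_count=len(bundle.patients))
    keep = []
    for p in bundle.patients:
        if p.age_at_switch < 18 or p.second_line_start is None:
            report.record(p.patient_id, "missing_data")
        elif p.switch_reason != "first_line_vf":
            report.record(p.patient_id, "switch_not_for_vf")
        else:
            keep.append(p.patient_id)
    return bundle.subset(keep), report


def exclude_zero_adherence_suppressed(
    bundle: CohortBundle,
    report: ExclusionReport | None = None,
    window_months: int = 4,
    suppression_threshold: float = 400,
    month_length_days: float | None = None,
) -> tuple[CohortBundle, ExclusionReport]:
    """Drop patients with a suppressed VL after a window of null adherence.

    A suppressed VL (below ``suppression_threshold`` copies/ml) with zero
    measured coverage over the preceding ``window_months`` implies the
    patient obtained medication elsewhere, so their recorded dispensing
    history does not reflect their true adherence.  Only VLs at least
    ``window_months`` after second-line start are considered, so the
    window never reaches back before therapy began.
    """
    if report is None:
        report = ExclusionReport(input_patient_count=len(bundle.patients))
    keep = []
    for p in bundle.patients:
        events = bundle.events_for(p.patient_id)
        flagged = False
        for vl in bundle.viral_loads_for(p.patient_id):
            if vl.copies_per_ml >= suppression_threshold:
                continue
            if vl.vl_date < add_months(p.second_line_start, window_months):
                continue
            interval = make_interval(
                p.patient_id, vl.vl_date, window_months, month_length_days
            )
            if interval_gap(events, interval).percent == 0.0:
                flagged = True
                break
        if flagged:
            report.record(p.patient_id, "suppressed_with_zero_adherence")
        else:
            keep.append(p.patient_id)
    return bundle.subset(keep), report


def select_observations(
    bundle: CohortBundle,
    report: ExclusionReport | None = None,
    min_months: int = 4,
    durations: Iterable[int] = DEFAULT_DURATIONS,
    methods: Iterable[str] = METHODS,
    month_length_days: float | None = None,
    crude_mode: str = "supply_weighted",
) -> tuple[list[AnalysisObservation], ExclusionReport]:
    """One observation per VL at least ``min_months`` (inclusive) after switch.

    Patients with no qualifying VL are counted under
    ``no_vl_after_4_months`` in the report.
    """
    if report is None:
        report = ExclusionReport(input_patient_count=len(bundle.patients))
    durations = list(durations)
    observations: list[AnalysisObservation] = []
    for p in bundle.patients:
        events = bundle.events_for(p.patient_id)
        threshold = add_months(p.second_line_start, min_months)
        qualifying = [
            vl for vl in bundle.viral_loads_for(p.patient_id) if vl.vl_date >= threshold
        ]
        if not qualifying:
            report.record(p.patient_id, "no_vl_after_4_months")
            continue
        first_year_end = add_months(p.second_line_start, 12)
        for vl in qualifying:
            grid = adherence_grid(
                events,
                p.second_line_start,
                vl.vl_date,
                durations=durations,
                methods=methods,
                month_length_days=month_length_days,
                crude_mode=crude_mode,
            )
            observations.append(AnalysisObservation(
                patient_id=p.patient_id,
                vl_date=vl.vl_date,
                copies_per_ml=vl.copies_per_ml,
                suppressed_50=vl.suppressed_50,
                suppressed_400=vl.suppressed_400,
                failure_1000=vl.failure_1000,
                months_on_second_line=months_on_art(p.second_line_start, vl.vl_date),
                time_band=(
                    "first_year" if vl.vl_date < first_year_end else "after_first_year"
                ),
                sex=p.sex,
                age_at_switch=p.age_at_switch,
                baseline_cd4=p.baseline_cd4,
                baseline_log10_vl=p.baseline_log10_vl,
                adherence=grid,
            ))
    return observations, report


def window_summaries(
    bundle: CohortBundle, windows: Sequence[int] = WINDOW_MONTHS
) -> list[WindowSummary]:
    """Suppression over time in six-monthly windows.

    A VL with months-on-therapy in ``[k-3, k+3)`` is assigned to window
    ``k`` (so a VL at 14.9 months is a 12-month VL, one at 15.0 months an
    18-month VL); when a patient has several VLs in one window, the one
    closest to the target month is used, earlier date winning exact ties.
    A patient is in care at window ``k`` if any dispensing or VL occurs at
    or after ``k-3`` months.
    """
    summaries = []
    for k in windows:
        lo, hi = k - WINDOW_HALF_WIDTH, k + WINDOW_HALF_WIDTH
        n_in_care = n_with_vl = n_lt50 = n_lt400 = n_ge1000 = 0
        for p in bundle.patients:
            start = p.second_line_start
            contacts = [
                months_on_art(start, e.dispense_date)
                for e in bundle.events_for(p.patient_id)
            ] + [
                months_on_art(start, v.vl_date)
                for v in bundle.viral_loads_for(p.patient_id)
            ]
            if any(m >= lo for m in contacts):
                n_in_care += 1
            in_window = [
                v
                for v in bundle.viral_loads_for(p.patient_id)
                if lo <= months_on_art(start, v.vl_date) < hi
            ]
            if not in_window:
                continue
            chosen = min(
                in_window,
                key=lambda v: (abs(months_on_art(start, v.vl_date) - k), v.vl_date),
            )
            n_with_vl += 1
            n_lt50 += chosen.suppressed_50
            n_lt400 += chosen.suppressed_400
            n_ge1000 += chosen.failure_1000
        summaries.append(WindowSummary(
            window_month=k,
            n_in_care=n_in_care,
            n_with_vl=n_with_vl,
            n_lt50=n_lt50,
            n_lt400=n_lt400,
            n_ge1000=n_ge1000,
        ))
    return summaries


def build_analysis_cohort(
    bundle: CohortBundle,
    min_months: int = 4,
    durations: Iterable[int] = DEFAULT_DURATIONS,
    methods: Iterable[str] = METHODS,
    suppression_threshold: float = 400,
    month_length_days: float | None = None,
    crude_mode: str = "supply_weighted",
) -> tuple[list[AnalysisObservation], ExclusionReport, CohortBundle]:
    """Run the full filter chain and anchor observations.

    Returns the observations, the cumulative exclusion report, and the
    retained bundle (useful for window summaries, which the published
    analysis computes before the zero-adherence exclusion).
    """
    filtered, report = apply_inclusion(bundle)
    filtered, report = exclude_zero_adherence_suppressed(
        filtered,
        report,
        window_months=min_months,
        suppression_threshold=suppression_threshold,
        month_length_days=month_length_days,
    )
    observations, report = select_observations(
        filtered,
        report,
        min_months=min_months,
        durations=durations,
        methods=methods,
        month_length_days=month_length_days,
        crude_mode=crude_mode,
    )
    return observations, report, filtered


def observations_frame(observations: Sequence[AnalysisObservation]) -> pd.DataFrame:
    """Flatten observations into a DataFrame, one adherence column per grid cell."""
    rows = []
    for obs in observations:
        row = {
            "patient_id": obs.patient_id,
            "vl_date": obs.vl_date.isoformat(),
            "copies_per_ml": obs.copies_per_ml,
            "suppressed_50": obs.suppressed_50,
            "suppressed_400": obs.suppressed_400,
            "failure_1000": obs.failure_1000,
            "months_on_second_line": obs.months_on_second_line,
            "time_band": obs.time_band,
            "sex": obs.sex,
            "age_at_switch": obs.age_at_switch,
            "baseline_cd4": obs.baseline_cd4,
            "cd4_imputed": obs.cd4_imputed,
            "baseline_log10_vl": obs.baseline_log10_vl,
            "log10_vl_imputed": obs.log10_vl_imputed,
            "sqrt_cd4": obs.sqrt_cd4,
        }
        for (method, duration), res in sorted(
            obs.adherence.items(), key=lambda kv: (kv[0][0], kv[0][1] or 0)
        ):
            label = method if duration is None else f"{method}_{duration}m"
            row[label] = res.percent
        rows.append(row)
    return pd.DataFrame(rows)
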