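"""Data model and CSV I/O for second-line ART refill cohorts.

Three delimited tables describe a cohort: a patient table (demographics and
baseline labs at second-line initiation), a dispensing-event table (one row
per pharmacy collection), and a viral-load table.  All dates are ISO-8601
calendar dates; every downstream adherence formula works on integer day
offsets, so date arithmetic is exact.
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import pandas as pd

SEXES = ("male", "female")
SWITCH_REASONS = ("first_line_vf", "toxicity", "other")

#: virologic thresholds in copies/ml
SUPPRESSION_50 = 50
SUPPRESSION_400 = 400
FAILURE_1000 = 1000


class CohortParseError(ValueError):
    """A cohort CSV could not be parsed; the message names file and line."""


def days_between(d1: date, d2: date) -> int:
    """Signed day count ``d2 - d1``."""
    return (d2 - d1).days


def add_months(d: date, months: int) -> date:
    """Shift ``d`` by calendar months, clamping the day to month end.

    ``add_months(2009-01-31, 1)`` is 2009-02-28: the day-of-month is kept
    where possible, otherwise clamped.  Negative shifts are allowed.
    """
    total = d.year * 12 + (d.month - 1) + months
    year, month = divmod(total, 12)
    month += 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return date(year, month, day)


@dataclass(frozen=True)
class PatientRecord:
    """One adult starting second-line (PI-based) ART."""

    patient_id: str
    sex: str
    age_at_switch: int
    second_line_start: date
    baseline_cd4: float | None = None  # cells/µL; None = missing, never 0
    baseline_log10_vl: float | None = None  # log10 copies/ml at switch
    switch_reason: str = "first_line_vf"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for {self.patient_id}")
        if self.switch_reason not in SWITCH_REASONS:
            raise ValueError(
                f"unknown switch_reason {self.switch_reason!r} for {self.patient_id}"
            )
        if self.baseline_cd4 is not None and self.baseline_cd4 < 0:
            raise ValueError(f"negative baseline CD4 for {self.patient_id}")


@dataclass(frozen=True)
class DispensingEvent:
    """One pharmacy collection: typically 30 days of medication, sometimes 60/90."""

    patient_id: str
    dispense_date: date
    days_supplied: int

    def __post_init__(self) -> None:
        if not 1 <= self.days_supplied <= 180:
            raise ValueError(
                f"days_supplied {self.days_supplied} outside [1, 180] "
                f"for {self.patient_id} on {self.dispense_date}"
            )

    @property
    def supply_end(self) -> date:
        """First day no longer covered by this collection (exclusive end)."""
        return self.dispense_date + timedelta(days=self.days_supplied)


@dataclass(frozen=True)
class ViralLoadResult:
    """One viral-load measurement with derived suppression/failure flags."""

    patient_id: str
    vl_date: date
    copies_per_ml: float

    def __post_init__(self) -> None:
        if self.copies_per_ml < 0:
            raise ValueError(f"negative copies/ml for {self.patient_id}")

    @property
    def suppressed_50(self) -> bool:
        return self.copies_per_ml < SUPPRESSION_50

    @property
    def suppressed_400(self) -> bool:
        return self.copies_per_ml < SUPPRESSION_400

    @property
    def failure_1000(self) -> bool:
        return self.copies_per_ml >= FAILURE_1000


@dataclass
class ReadReport:
    """Bookkeeping from read_cohort: rejected and merged rows."""

    unknown_patient_rows: int = 0
    merged_duplicate_events: int = 0


@dataclass
class CohortBundle:
    """A validated cohort: patients plus their dispensing and VL histories.

    Events are kept sorted ascending by date within each patient; every
    event/VL patient_id refers to a known patient.
    """

    patients: list[PatientRecord]
    events: list[DispensingEvent]
    viral_loads: list[ViralLoadResult]
    read_report: ReadReport = field(default_factory=ReadReport)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient_id in patient table")
        known = set(ids)
        for ev in self.events:
            if ev.patient_id not in known:
                raise ValueError(f"event for unknown patient {ev.patient_id}")
        for vl in self.viral_loads:
            if vl.patient_id not in known:
                raise ValueError(f"viral load for unknown patient {vl.patient_id}")
        self.events = sorted(self.events, key=lambda e: (e.patient_id, e.dispense_date))
        self.viral_loads = sorted(self.viral_loads, key=lambda v: (v.patient_id, v.vl_date))

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def events_for(self, patient_id: str) -> list[DispensingEvent]:
        return [e for e in self.events if e.patient_id == patient_id]

    def viral_loads_for(self, patient_id: str) -> list[ViralLoadResult]:
        return [v for v in self.viral_loads if v.patient_id == patient_id]

    def subset(self, patient_ids) -> "CohortBundle":
        """Restrict to the given patients, dropping their absent rows."""
        keep = set(patient_ids)
        return CohortBundle(
            patients=[p for p in self.patients if p.patient_id in keep],
            events=[e for e in self.events if e.patient_id in keep],
            viral_loads=[v for v in self.viral_loads if v.patient_id in keep],
            read_report=self.read_report,
        )


def _parse_date(value: str, path: str, line: int, column: str) -> date:
    try:
        return date.fromisoformat(str(value).strip())
    except (ValueError, TypeError) as exc:
        raise CohortParseError(
            f"{path}:{line}: malformed date {value!r} in column {column}"
        ) from exc


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return None if s == "" else float(s)


PATIENT_COLUMNS = [
    "patient_id", "sex", "age_at_switch", "second_line_start",
    "baseline_cd4", "baseline_log10_vl", "switch_reason",
]
EVENT_COLUMNS = ["patient_id", "dispense_date", "days_supplied"]
VL_COLUMNS = ["patient_id", "vl_date", "copies_per_ml"]


def _read_table(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing column(s) {missing}")
    return df


def read_cohort(patient_path, events_path, vl_path) -> CohortBundle:
    """Read and validate the three cohort CSVs.

    Dispensing rows that duplicate (patient, date) are merged by summing
    days_supplied (a patient may collect more than one month's supply at a
    single visit); event/VL rows that reference a patient absent from the
    patient table are dropped.  Both counts are recorded on the returned
    bundle's ``read_report``.
    """
    report = ReadReport()

    pdf = _read_table(patient_path, PATIENT_COLUMNS)
    patients = []
    for i, row in enumerate(pdf.itertuples(index=False), start=2):
        patients.append(PatientRecord(
            patient_id=row.patient_id,
            sex=row.sex,
            age_at_switch=int(row.age_at_switch),
            second_line_start=_parse_date(
                row.second_line_start, str(patient_path), i, "second_line_start"),
            baseline_cd4=_opt_float(row.baseline_cd4),
            baseline_log10_vl=_opt_float(row.baseline_log10_vl),
            switch_reason=row.switch_reason,
        ))
    known = {p.patient_id for p in patients}

    edf = _read_table(events_path, EVENT_COLUMNS)
    merged: dict[tuple[str, date], int] = {}
    for i, row in enumerate(edf.itertuples(index=False), start=2):
        if row.patient_id not in known:
            report.unknown_patient_rows += 1
            continue
        d = _parse_date(row.dispense_date, str(events_path), i, "dispense_date")
        key = (row.patient_id, d)
        if key in merged:
            report.merged_duplicate_events += 1
            warnings.warn(
                f"duplicate dispensing for {row.patient_id} on {d}; days summed",
                stacklevel=2,
            )
        merged[key] = merged.get(key, 0) + int(row.days_supplied)
    events = [
        DispensingEvent(pid, d, supplied) for (pid, d), supplied in merged.items()
    ]

    vdf = _read_table(vl_path, VL_COLUMNS)
    vls = []
    for i, row in enumerate(vdf.itertuples(index=False), start=2):
        if row.patient_id not in known:
            report.unknown_patient_rows += 1
            continue
        vls.append(ViralLoadResult(
            patient_id=row.patient_id,
            vl_date=_parse_date(row.vl_date, str(vl_path), i, "vl_date"),
            copies_per_ml=float(row.copies_per_ml),
        ))

    return CohortBundle(patients, events, vls, read_report=report)


def _fmt_opt(x: float | None) -> str:
    if x is None:
        return ""
    return repr(float(x))


def write_cohort(bundle: CohortBundle, directory) -> dict[str, Path]:
    """Write the three cohort CSVs into ``directory``; returns their paths.

    Inverse of :func:`read_cohort` field-for-field, including missing
    baseline values (written as empty cells).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": directory / "patients.csv",
        "events": directory / "events.csv",
        "viral_loads": directory / "viral_loads.csv",
    }
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "age_at_switch": p.age_at_switch,
                "second_line_start": p.second_line_start.isoformat(),
                "baseline_cd4": _fmt_opt(p.baseline_cd4),
                "baseline_log10_vl": _fmt_opt(p.baseline_log10_vl),
                "switch_reason": p.switch_reason,
            }
            for p in bundle.patients
        ],
        columns=PATIENT_COLUMNS,
    ).to_csv(paths["patients"], index=False)
    pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "dispense_date": e.dispense_date.isoformat(),
                "days_supplied": e.days_supplied,
            }
            for e in bundle.events
        ],
        columns=EVENT_COLUMNS,
    ).to_csv(paths["events"], index=False)
    pd.DataFrame(
        [
            {
                "patient_id": v.patient_id,
                "vl_date": v.vl_date.isoformat(),
                "copies_per_ml": repr(float(v.copies_per_ml)),
            }
            for v in bundle.viral_loads
        ],
        columns=VL_COLUMNS,
    ).to_csv(paths["viral_loads"], index=False)
    return paths
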