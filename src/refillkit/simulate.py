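"""Synthetic second-line ART dispensing cohorts with known ground truth.

The generator emulates the dispensing mechanics of a South African ART
clinic: a 30-day supply collected at refills scheduled every 28 days (the
two-day buffer is why perfectly adherent patients accumulate surplus),
with stable suppressed patients occasionally issued 60 or 90 days;
six-monthly viral-load monitoring with some jitter; and per-patient
refill-attendance propensities drawn from a Beta distribution, so missed
collections — not per-day pill-taking — create coverage gaps.

Virologic failure at each VL is Bernoulli with a logistic risk that
depends on the patient's *true* daily coverage over the preceding four
months (computed from the generator's own possession walk, never from an
estimator under evaluation) plus baseline covariates.  The coefficient
vector, per-patient propensities, and per-VL true coverage are returned as
ground truth for parameter-recovery testing.

Baseline marginals are calibrated to a typical second-line cohort:
median CD4 near 174 cells/µL, median log10 VL near 4.1, median age 35,
54% female, median follow-up around 27 months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CohortBundle,
    DispensingEvent,
    PatientRecord,
    ViralLoadResult,
    days_between,
    write_cohort,
)

DAYS_PER_MONTH = 365.25 / 12


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class OutcomeCoefficients:
    """Log-odds of virologic failure; covariates centred at a reference patient.

    The reference is 85% coverage, sqrt-CD4 13 (≈169 cells/µL), log10 VL
    4.1, female, age 26+, within the first year — so ``intercept`` is the
    failure log-odds of that reference patient.
    """

    intercept: float = -2.2  # ≈10% failure at the reference point
    adherence_per10: float = -0.7  # per 10 percentage points of true coverage
    sqrt_cd4: float = -0.22
    log10_vl: float = 0.5
    after_first_year: float = 0.5
    male: float = 0.3
    age_under_26: float = 0.4

    # centring constants
    coverage_ref: float = 85.0
    sqrt_cd4_ref: float = 13.0
    log10_vl_ref: float = 4.1

    def failure_probability(
        self,
        coverage_percent: float,
        sqrt_cd4: float,
        log10_vl: float,
        after_first_year: bool,
        male: bool,
        age_under_26: bool,
    ) -> float:
        lp = (
            self.intercept
            + self.adherence_per10 * (coverage_percent - self.coverage_ref) / 10.0
            + self.sqrt_cd4 * (sqrt_cd4 - self.sqrt_cd4_ref)
            + self.log10_vl * (log10_vl - self.log10_vl_ref)
            + self.after_first_year * after_first_year
            + self.male * male
            + self.age_under_26 * age_under_26
        )
        return _logistic(lp)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the clinic's dispensing conventions (28-day refill
    schedule, 30-day supplies, occasional 60/90-day supplies for stable
    suppressed patients) and the baseline marginals described above.
    """

    n_patients: int = 500
    seed: int = 20141204

    # enrolment and follow-up
    enrolment_start: date = date(2003, 8, 1)
    enrolment_span_days: int = 2860  # ≈ Aug 2003 – June 2011
    follow_up_median_months: float = 27.0
    follow_up_sigma: float = 0.85  # log-scale spread; IQR ≈ 15–47 months
    follow_up_min_months: float = 5.0
    follow_up_max_months: float = 96.0

    # dispensing mechanics
    refill_interval_days: int = 28
    supply_days: int = 30
    p_long_supply: float = 0.08  # when last VL suppressed; 60 or 90 days equally
    gap_mean_days: float = 21.0  # mean extra delay after a missed refill
    adherence_alpha: float = 5.0  # Beta prior on refill-attendance propensity
    adherence_beta: float = 1.2

    # VL monitoring
    vl_interval_months: float = 6.0
    vl_jitter_days: float = 21.0

    # baseline covariates
    p_female: float = 0.544
    age_median: float = 35.0
    age_sigma: float = 0.20
    cd4_median: float = 174.0
    cd4_sigma: float = 0.672  # log-scale; IQR ≈ 107–265
    log10_vl_mean: float = 4.1
    log10_vl_sd: float = 0.815  # IQR ≈ 3.6–4.7
    missing_cd4_rate: float = 0.084
    missing_log10_vl_rate: float = 0.047
    p_non_vf_switch: float = 0.05  # toxicity/other switches, removed by filters

    # patients collecting ART elsewhere: suppressed despite empty local record
    transfer_in_rate: float = 0.03

    # copies/ml mixture (log10 scale) for suppressed vs failing states
    suppressed_log10_mean: float = 1.3
    suppressed_log10_sd: float = 0.5
    failure_log10_mean: float = 4.2
    failure_log10_sd: float = 0.6

    coefficients: OutcomeCoefficients = field(default_factory=OutcomeCoefficients)
    risk_window_months: int = 4

    def validate(self) -> None:
        problems = []
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        for name in (
            "p_long_supply", "p_female", "missing_cd4_rate",
            "missing_log10_vl_rate", "p_non_vf_switch", "transfer_in_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be a probability, got {v}")
        for name in ("refill_interval_days", "supply_days", "gap_mean_days",
                     "adherence_alpha", "adherence_beta", "vl_interval_months"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass
class SyntheticGroundTruth:
    """What the generator knows: propensities, true coverage, coefficients."""

    propensity: dict[str, float]  # patient_id -> refill-attendance probability
    true_coverage: dict[tuple[str, date], float]  # (patient, vl_date) -> %
    coefficients: OutcomeCoefficients = field(default_factory=OutcomeCoefficients)
    is_transfer: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": pid,
                "vl_date": d.isoformat(),
                "propensity": self.propensity[pid],
                "true_coverage_percent": cov,
                "is_transfer": self.is_transfer.get(pid, False),
            }
            for (pid, d), cov in sorted(self.true_coverage.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id", "vl_date", "propensity",
                "true_coverage_percent", "is_transfer",
            ],
        )


def _true_coverage(
    events: list[DispensingEvent], window_start: date, window_end: date
) -> float:
    """Possession walk over [window_start, window_end): % of days with medication.

    Carry-in from the most recent collection before the window; surplus
    carries forward uncapped, never backward.
    """
    n = days_between(window_start, window_end)
    supply_on: dict[int, int] = {}
    balance = 0
    for ev in events:
        off = days_between(window_start, ev.dispense_date)
        if off < 0:
            balance = max(0, ev.days_supplied + off)  # keep only the latest prior
        elif off < n:
            supply_on[off] = supply_on.get(off, 0) + ev.days_supplied
    covered = 0
    for d in range(n):
        balance += supply_on.get(d, 0)
        if balance >= 1:
            covered += 1
            balance -= 1
    return 100.0 * covered / n


def generate(config: GeneratorConfig) -> tuple[CohortBundle, SyntheticGroundTruth]:
    """Simulate a dispensing cohort; reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    coeffs = config.coefficients

    patients: list[PatientRecord] = []
    events: list[DispensingEvent] = []
    vls: list[ViralLoadResult] = []
    truth = SyntheticGroundTruth(propensity={}, true_coverage={}, coefficients=coeffs)

    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        start = config.enrolment_start + timedelta(
            days=int(rng.integers(0, config.enrolment_span_days + 1))
        )
        followup_months = float(np.clip(
            config.follow_up_median_months
            * math.exp(rng.normal(0.0, config.follow_up_sigma)),
            config.follow_up_min_months,
            config.follow_up_max_months,
        ))
        followup_days = int(round(followup_months * DAYS_PER_MONTH))

        sex = "female" if rng.random() < config.p_female else "male"
        age = int(np.clip(
            round(config.age_median * math.exp(rng.normal(0.0, config.age_sigma))),
            18, 80,
        ))
        cd4 = float(np.clip(
            config.cd4_median * math.exp(rng.normal(0.0, config.cd4_sigma)), 1.0, 1500.0
        ))
        lvl = float(np.clip(rng.normal(config.log10_vl_mean, config.log10_vl_sd), 2.0, 7.0))
        cd4_missing = rng.random() < config.missing_cd4_rate
        lvl_missing = rng.random() < config.missing_log10_vl_rate
        non_vf = rng.random() < config.p_non_vf_switch
        reason = (
            ("toxicity" if rng.random() < 0.7 else "other") if non_vf else "first_line_vf"
        )
        theta = float(rng.beta(config.adherence_alpha, config.adherence_beta))
        is_transfer = rng.random() < config.transfer_in_rate
        truth.propensity[pid] = 0.0 if is_transfer else theta
        truth.is_transfer[pid] = is_transfer

        patients.append(PatientRecord(
            patient_id=pid,
            sex=sex,
            age_at_switch=age,
            second_line_start=start,
            baseline_cd4=None if cd4_missing else round(cd4),
            baseline_log10_vl=None if lvl_missing else round(lvl, 1),
            switch_reason=reason,
        ))

        # --- dispensing walk -------------------------------------------------
        my_events: list[DispensingEvent] = []
        last_vl_suppressed = True
        t = 0  # day offset of the next scheduled collection
        if not is_transfer:
            while t < followup_days:
                if t > 0 and rng.random() >= theta:
                    # missed refill: geometric extra delay before attending
                    t += 1 + int(rng.geometric(1.0 / config.gap_mean_days))
                    if t >= followup_days:
                        break
                supply = config.supply_days
                if last_vl_suppressed and rng.random() < config.p_long_supply:
                    supply = 60 if rng.random() < 0.5 else 90
                my_events.append(DispensingEvent(
                    pid, start + timedelta(days=t), supply
                ))
                # next collection scheduled two days before supply runs out
                t += supply - (config.supply_days - config.refill_interval_days)

        # --- VL monitoring ---------------------------------------------------
        t_vl = config.vl_interval_months * DAYS_PER_MONTH
        while t_vl < followup_days:
            offset = int(round(t_vl + rng.normal(0.0, config.vl_jitter_days)))
            if offset < 30:
                offset = 30
            vl_date = start + timedelta(days=offset)
            window_months = config.risk_window_months
            window_days = int(round(window_months * DAYS_PER_MONTH))
            window_start = max(start, vl_date - timedelta(days=window_days))
            coverage = _true_coverage(my_events, window_start, vl_date)
            truth.true_coverage[(pid, vl_date)] = coverage

            if is_transfer:
                failed = rng.random() < 0.08  # suppressed elsewhere, usually
            else:
                p_fail = coeffs.failure_probability(
                    coverage_percent=coverage,
                    sqrt_cd4=math.sqrt(cd4),
                    log10_vl=lvl,
                    after_first_year=offset > 365,
                    male=sex == "male",
                    age_under_26=age < 26,
                )
                failed = rng.random() < p_fail
            if failed:
                log10_copies = max(3.0, rng.normal(
                    config.failure_log10_mean, config.failure_log10_sd))
            else:
                log10_copies = min(math.log10(399.0), rng.normal(
                    config.suppressed_log10_mean, config.suppressed_log10_sd))
            vls.append(ViralLoadResult(pid, vl_date, round(10 ** log10_copies, 1)))
            last_vl_suppressed = not failed
            t_vl += config.vl_interval_months * DAYS_PER_MONTH

        events.extend(my_events)

    bundle = CohortBundle(patients, events, vls)
    return bundle, truth


def fixture_bundle() -> CohortBundle:
    """Four hand-built patients exercising one pipeline rule each.

    * F_PERFECT — collects 30 days every 28 days for a year; suppressed.
    * F_HALF    — collects on days 0 and 56 only; VL four months in
      (the classic 50%-adherence worked example).
    * F_GHOST   — one collection at the switch, then nothing, yet a
      suppressed VL at six months: removed by the zero-adherence rule.
    * F_TOX     — switched for toxicity: removed by the switch-reason rule.
    """
    start = date(2009, 1, 1)
    patients = [
        PatientRecord("F_PERFECT", "female", 35, start, 250.0, 4.0, "first_line_vf"),
        PatientRecord("F_HALF", "male", 41, start, 174.0, 4.1, "first_line_vf"),
        PatientRecord("F_GHOST", "female", 29, start, None, 3.8, "first_line_vf"),
        PatientRecord("F_TOX", "male", 52, start, 320.0, None, "toxicity"),
    ]
    events = (
        [
            DispensingEvent("F_PERFECT", start + timedelta(days=28 * k), 30)
            for k in range(13)
        ]
        + [
            DispensingEvent("F_HALF", start, 30),
            DispensingEvent("F_HALF", start + timedelta(days=56), 30),
        ]
        + [DispensingEvent("F_GHOST", start, 30)]
        + [DispensingEvent("F_TOX", start + timedelta(days=28 * k), 30) for k in range(4)]
    )
    vls = [
        ViralLoadResult("F_PERFECT", date(2009, 7, 1), 40.0),
        ViralLoadResult("F_PERFECT", date(2010, 1, 1), 38.0),
        ViralLoadResult("F_HALF", date(2009, 5, 1), 15000.0),
        ViralLoadResult("F_GHOST", date(2009, 7, 1), 45.0),
        ViralLoadResult("F_TOX", date(2009, 7, 1), 60.0),
    ]
    return CohortBundle(patients, events, vls)


def make_fixtures(directory) -> dict[str, Path]:
    """Write the worked fixtures as the three cohort CSVs; deterministic."""
    return write_cohort(fixture_bundle(), directory)
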