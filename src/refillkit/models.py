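"""Statistical evaluation of adherence measures against virologic outcomes.

ROC discrimination (Mann–Whitney AUC with DeLong or bootstrap confidence
intervals), adherence-bin dose response with Wilson intervals, baseline
imputation, and univariate/multivariate logistic regression for risk
factors of virologic failure.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import AnalysisObservation, ExclusionReport
from .metrics import DEFAULT_DURATIONS, METHODS

DEFAULT_SEED = 20141204
DEFAULT_BIN_EDGES = (0, 20, 40, 60, 80, 90, 100)

OUTCOME_DEFINITIONS = ("suppressed_400", "suppressed_50", "failure_1000")


class SingleClassError(ValueError):
    """ROC analysis needs at least one positive and one negative outcome."""


class SeparationError(ValueError):
    """The logistic likelihood is unbounded (perfect separation or constant outcome)."""


@dataclass(frozen=True)
class RocResult:
    method: str
    duration_months: int | None  # None = long-term overall
    outcome_definition: str
    auc: float
    ci_low: float
    ci_high: float
    n_observations: int

    @property
    def duration_label(self) -> str:
        return "overall" if self.duration_months is None else f"{self.duration_months}m"


@dataclass(frozen=True)
class DoseResponseBin:
    adherence_bin: str
    lower: float
    upper: float
    n: int
    n_positive: int
    proportion_positive: float | None
    ci_upper_95: float | None


@dataclass(frozen=True)
class RegressionResult:
    variable: str
    scale_note: str
    estimate: float | None  # log-odds; None for reference categories
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    model: str  # "univariate" | "multivariate"

    @property
    def odds_ratio(self) -> float | None:
        return None if self.estimate is None else math.exp(self.estimate)


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(score of a positive > score of a negative), ties counted half."""
    neg_sorted = np.sort(neg)
    less = np.searchsorted(neg_sorted, pos, side="left")
    less_eq = np.searchsorted(neg_sorted, pos, side="right")
    return float((less + 0.5 * (less_eq - less)).sum() / (len(pos) * len(neg)))


def _placements(x: np.ndarray, other: np.ndarray) -> np.ndarray:
    """DeLong structural components: per-element mid-rank placement vs `other`."""
    other_sorted = np.sort(other)
    less = np.searchsorted(other_sorted, x, side="left")
    less_eq = np.searchsorted(other_sorted, x, side="right")
    return (less + 0.5 * (less_eq - less)) / len(other)


def roc_auc(
    scores: Sequence[float],
    outcomes: Sequence[bool],
    method: str = "",
    duration_months: int | None = None,
    outcome_definition: str = "suppressed_400",
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = DEFAULT_SEED,
) -> RocResult:
    """AUC of a score for a binary outcome, with a 95% confidence interval.

    The AUC is the Mann–Whitney concordance probability: the chance that a
    randomly chosen positive observation carries a higher score than a
    randomly chosen negative one, ties counted one half.  The default CI
    uses the DeLong asymptotic variance; ``ci_method="bootstrap"`` resamples
    observations (``n_boot`` stratified replicates, seeded) instead.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    if scores.shape != outcomes.shape:
        raise ValueError("scores and outcomes must have equal length")
    pos = scores[outcomes]
    neg = scores[~outcomes]
    if len(pos) == 0 or len(neg) == 0:
        raise SingleClassError(
            f"ROC needs both outcome classes; got {len(pos)} positive and "
            f"{len(neg)} negative observations"
        )
    auc = _auc_mann_whitney(pos, neg)
    if ci_method == "delong":
        v10 = _placements(pos, neg)  # per-positive
        v01 = 1.0 - _placements(neg, pos)  # per-negative
        var = 0.0
        if len(pos) > 1:
            var += np.var(v10, ddof=1) / len(pos)
        if len(neg) > 1:
            var += np.var(v01, ddof=1) / len(neg)
        half = norm.ppf(0.975) * math.sqrt(var)
        lo, hi = auc - half, auc + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            p = pos[rng.integers(0, len(pos), len(pos))]
            n = neg[rng.integers(0, len(neg), len(neg))]
            reps[b] = _auc_mann_whitney(p, n)
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RocResult(
        method=method,
        duration_months=duration_months,
        outcome_definition=outcome_definition,
        auc=auc,
        ci_low=float(max(0.0, min(lo, auc))),
        ci_high=float(min(1.0, max(hi, auc))),
        n_observations=len(scores),
    )


def _outcome_flags(observations, outcome_definition: str) -> np.ndarray:
    """Positive class per outcome definition.

    For the suppression outcomes the positive class is the suppressed VL.
    For ``failure_1000`` the positive class is *absence* of failure, so a
    discriminating adherence score always yields AUC above one half and
    the three definitions are directly comparable.
    """
    if outcome_definition == "suppressed_400":
        return np.array([o.suppressed_400 for o in observations])
    if outcome_definition == "suppressed_50":
        return np.array([o.suppressed_50 for o in observations])
    if outcome_definition == "failure_1000":
        return np.array([not o.failure_1000 for o in observations])
    raise ValueError(f"unknown outcome definition {outcome_definition!r}")


def method_duration_grid(
    observations: Sequence[AnalysisObservation],
    methods: Iterable[str] = METHODS,
    durations: Iterable[int] = DEFAULT_DURATIONS,
    outcome_definition: str = "suppressed_400",
    include_overall: bool = True,
    ci_method: str = "delong",
    seed: int = DEFAULT_SEED,
) -> list[RocResult]:
    """One AUC per (method, duration) cell, plus the long-term overall measure."""
    seen: list[str] = []
    for m in methods:
        if m in seen:
            warnings.warn(f"duplicate method {m!r} dropped", stacklevel=2)
        else:
            seen.append(m)
    outcomes = _outcome_flags(observations, outcome_definition)
    results = []
    for m in seen:
        for d in durations:
            scores = [o.adherence_percent(m, d) for o in observations]
            results.append(roc_auc(
                scores, outcomes, method=m, duration_months=d,
                outcome_definition=outcome_definition, ci_method=ci_method, seed=seed,
            ))
    if include_overall:
        scores = [o.adherence_percent("overall", None) for o in observations]
        results.append(roc_auc(
            scores, outcomes, method="overall", duration_months=None,
            outcome_definition=outcome_definition, ci_method=ci_method, seed=seed,
        ))
    return results


def dose_response(
    observations: Sequence[AnalysisObservation],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    outcome_definition: str = "suppressed_400",
    method: str = "interval_gap",
    duration_months: int = 4,
) -> list[DoseResponseBin]:
    """Proportion with the favourable outcome per adherence stratum.

    Bins are right-open except the last, which is right-closed at 100 so a
    perfectly adherent patient falls in the top stratum.  Empty bins are
    reported with n=0 and null proportion rather than dropped — the sparse
    low-adherence strata are themselves informative.  The upper bound is
    the Wilson 95% limit.
    """
    edges = list(bin_edges)
    if edges != sorted(set(edges)) or edges[0] != 0 or edges[-1] != 100:
        raise ValueError("bin_edges must be strictly increasing and span [0, 100]")
    outcomes = _outcome_flags(observations, outcome_definition)
    scores = np.array([o.adherence_percent(method, duration_months) for o in observations])
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi == 100:
            mask = (scores >= lo) & (scores <= hi)
            label = f"{lo:g}-{hi:g}"
        else:
            mask = (scores >= lo) & (scores < hi)
            label = f"{lo:g}-<{hi:g}"
        n = int(mask.sum())
        k = int(outcomes[mask].sum())
        if n == 0:
            bins.append(DoseResponseBin(label, lo, hi, 0, 0, None, None))
        else:
            upper = proportion_confint(k, n, alpha=0.05, method="wilson")[1]
            bins.append(DoseResponseBin(label, lo, hi, n, k, k / n, float(upper)))
    return bins


def impute_baseline(
    observations: Sequence[AnalysisObservation], strategy: str = "median"
) -> list[AnalysisObservation]:
    """Fill missing baseline CD4 / log10 VL with a cohort statistic.

    The statistic is computed over non-missing *patients* (each patient
    counted once, however many VL observations they contribute), then the
    same imputed value is reused across all of a patient's observations.
    Imputation flags are set on the returned copies; sqrt-CD4 follows from
    the imputed CD4 automatically.
    """
    if strategy not in ("median", "mean"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    stat = np.median if strategy == "median" else np.mean

    per_patient_cd4: dict[str, float | None] = {}
    per_patient_lvl: dict[str, float | None] = {}
    for o in observations:
        per_patient_cd4.setdefault(o.patient_id, o.baseline_cd4)
        per_patient_lvl.setdefault(o.patient_id, o.baseline_log10_vl)

    def fill_value(values: dict[str, float | None], name: str) -> float:
        known = [v for v in values.values() if v is not None]
        if not known:
            raise ValueError(f"cannot impute {name}: no non-missing patients")
        return float(stat(known))

    cd4_fill = (
        fill_value(per_patient_cd4, "baseline_cd4")
        if any(v is None for v in per_patient_cd4.values())
        else None
    )
    lvl_fill = (
        fill_value(per_patient_lvl, "baseline_log10_vl")
        if any(v is None for v in per_patient_lvl.values())
        else None
    )

    out = []
    for o in observations:
        new = o
        if o.baseline_cd4 is None:
            new = replace(new, baseline_cd4=cd4_fill, cd4_imputed=True)
        if o.baseline_log10_vl is None:
            new = replace(new, baseline_log10_vl=lvl_fill, log10_vl_imputed=True)
        out.append(new)
    return out


#: covariates of the risk-factor model: (column, scale note)
DEFAULT_COVARIATES = (
    ("adherence_per10", "interval_gap over 4 months, per 10 percentage points"),
    ("after_first_year", "time on second line: after first year vs first year"),
    ("male", "sex: male vs female"),
    ("age_under_26", "age at switch: <26 vs >=26 years"),
    ("baseline_log10_vl", "log10 VL at second-line initiation"),
    ("sqrt_cd4", "square-root CD4 (cells/uL) at second-line initiation"),
)

_REFERENCE_ROWS = {
    "after_first_year": ("time_first_year", "time on second line: first year (referent)"),
    "male": ("sex_female", "sex: female (referent)"),
    "age_under_26": ("age_26_plus", "age at switch: >=26 years (referent)"),
}


def design_matrix(
    observations: Sequence[AnalysisObservation],
    adherence_method: str = "interval_gap",
    adherence_duration: int = 4,
) -> pd.DataFrame:
    """Regression design: outcome ``failure_1000`` plus the standard covariates.

    Adherence enters per 10 percentage points; CD4 enters on the square-root
    scale to attenuate the influence of high counts.  Requires imputation
    (or complete data): missing baselines raise.
    """
    rows = []
    for o in observations:
        if o.baseline_cd4 is None or o.baseline_log10_vl is None:
            raise ValueError(
                f"missing baseline covariates for {o.patient_id}; run impute_baseline first"
            )
        rows.append({
            "patient_id": o.patient_id,
            "failure_1000": int(o.failure_1000),
            "adherence_per10": o.adherence_percent(adherence_method, adherence_duration) / 10.0,
            "after_first_year": int(o.time_band == "after_first_year"),
            "male": int(o.sex == "male"),
            "age_under_26": int(o.age_at_switch < 26),
            "baseline_log10_vl": o.baseline_log10_vl,
            "sqrt_cd4": o.sqrt_cd4,
        })
    return pd.DataFrame(rows)


def _fit_one(y, X, penalized: bool, groups=None):
    model = sm.Logit(y, X)
    if penalized:
        # ridge fallback for separated designs; Wald CIs are not available
        return model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=0), False
    fit_kwargs = {"disp": 0, "maxiter": 200}
    if groups is not None:
        fit_kwargs.update(cov_type="cluster", cov_kwds={"groups": groups})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = model.fit(**fit_kwargs)
    except (
        PerfectSeparationError,
        PerfectSeparationWarning,
        np.linalg.LinAlgError,
        RuntimeWarning,
    ) as exc:
        raise SeparationError(
            "logistic fit failed (separation or singular design); "
            "retry with penalized=True"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge; retry with penalized=True")
    return res, True


def fit_logistic(
    observations: Sequence[AnalysisObservation],
    covariates: Sequence[tuple[str, str]] = DEFAULT_COVARIATES,
    adherence_method: str = "interval_gap",
    adherence_duration: int = 4,
    cluster_robust: bool = False,
    penalized: bool = False,
) -> list[RegressionResult]:
    """Univariate and multivariate logistic regressions for virologic failure.

    Univariate models fit one covariate at a time on the same observation
    set; the multivariate model includes all covariates.  Estimates are
    log-odds with 95% Wald intervals.  ``cluster_robust=True`` clusters
    standard errors by patient (repeated VLs per patient); the default
    treats observations as independent.
    """
    df = design_matrix(observations, adherence_method, adherence_duration)
    y = df["failure_1000"]
    if y.nunique() < 2:
        raise SeparationError("outcome is constant; the logistic model is undefined")

    results: list[RegressionResult] = []
    groups = (
        df["patient_id"].astype("category").cat.codes.to_numpy()
        if cluster_robust
        else None
    )

    def extract(res, have_cov, names, model_label):
        params = np.asarray(res.params).ravel()
        index = list(X_cols)
        if have_cov:
            conf = np.asarray(res.conf_int())
            pvals = np.asarray(res.pvalues).ravel()
        for name, note in names:
            i = index.index(name)
            if have_cov:
                results.append(RegressionResult(
                    name, note, float(params[i]),
                    float(conf[i, 0]), float(conf[i, 1]), float(pvals[i]), model_label,
                ))
            else:
                results.append(RegressionResult(
                    name, note, float(params[i]), None, None, None, model_label,
                ))
            ref = _REFERENCE_ROWS.get(name)
            if ref is not None:
                results.append(RegressionResult(
                    ref[0], ref[1], None, None, None, None, model_label,
                ))

    for name, note in covariates:
        X = sm.add_constant(df[[name]])
        X_cols = list(X.columns)
        res, have_cov = _fit_one(y, X, penalized, groups)
        extract(res, have_cov, [(name, note)], "univariate")

    X = sm.add_constant(df[[name for name, _ in covariates]])
    X_cols = list(X.columns)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = df[[name for name, _ in covariates]].corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"singular design matrix; check collinear variables {worst}")
    res, have_cov = _fit_one(y, X, penalized, groups)
    extract(res, have_cov, list(covariates), "multivariate")
    return results


def report(
    out_dir,
    roc_results: Sequence[RocResult],
    dose_bins: Sequence[DoseResponseBin],
    regression_results: Sequence[RegressionResult],
    exclusion_report: ExclusionReport,
    window_rows: Sequence = (),
    summary_lines: Sequence[str] = (),
) -> dict[str, Path]:
    """Write the analysis outputs as CSV/JSON plus a plain-text summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["roc_grid"] = out_dir / "roc_grid.csv"
    pd.DataFrame([
        {
            "method": r.method,
            "duration": r.duration_label,
            "outcome": r.outcome_definition,
            "auc": r.auc,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "n": r.n_observations,
        }
        for r in roc_results
    ]).to_csv(paths["roc_grid"], index=False)

    paths["dose_response"] = out_dir / "dose_response.csv"
    pd.DataFrame([
        {
            "adherence_bin": b.adherence_bin,
            "n": b.n,
            "n_positive": b.n_positive,
            "proportion_positive": b.proportion_positive,
            "ci_upper_95": b.ci_upper_95,
        }
        for b in dose_bins
    ]).to_csv(paths["dose_response"], index=False)

    paths["regression"] = out_dir / "regression.csv"
    pd.DataFrame([
        {
            "variable": r.variable,
            "scale": r.scale_note,
            "model": r.model,
            "log_odds": r.estimate,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
            "odds_ratio": r.odds_ratio,
        }
        for r in regression_results
    ]).to_csv(paths["regression"], index=False)

    paths["exclusion_report"] = out_dir / "exclusion_report.json"
    paths["exclusion_report"].write_text(
        json.dumps(exclusion_report.as_dict(), indent=2) + "\n"
    )

    if window_rows:
        paths["window_summary"] = out_dir / "window_summary.csv"
        pd.DataFrame([
            {
                "window_month": w.window_month,
                "n_in_care": w.n_in_care,
                "n_with_vl": w.n_with_vl,
                "n_lt50": w.n_lt50,
                "pct_lt50": w.pct_lt50,
                "n_lt400": w.n_lt400,
                "pct_lt400": w.pct_lt400,
                "n_ge1000": w.n_ge1000,
                "pct_ge1000": w.pct_ge1000,
            }
            for w in window_rows
        ]).to_csv(paths["window_summary"], index=False)

    paths["summary"] = out_dir / "summary.txt"
    paths["summary"].write_text("\n".join(summary_lines) + "\n")
    return paths
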