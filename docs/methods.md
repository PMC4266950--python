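# Methods

## The estimation problem

Pharmacy dispensing records give, for each patient, the dates on which
medication was collected and the number of days supplied each time. The
package turns such a record into an adherence percentage over a window
ending at a viral load (VL), and evaluates how well each way of doing
that predicts the virologic outcome. The unit of analysis throughout is
the VL measurement, not the patient: each VL drawn at least four months
after second-line initiation contributes one observation, joined to the
adherence computed over the windows ending on its date and to the
patient's baseline covariates. Repeated VLs per patient are treated as
independent by default; cluster-robust (by patient) standard errors are
available as an option in the regression.

## Windows and date arithmetic

Dates are calendar dates; every formula operates on exact integer day
counts, so all adherence arithmetic is reproducible to the day. A window
of *m* months ending at a VL on date *e* runs over the half-open range
`[e − m calendar months, e)`: the day-of-month is preserved where
possible (clamped to month end), and the VL day itself is excluded, so
adherence is always measured strictly before the outcome it predicts. A
fixed mean month length (30.4375 days) is available via
`month_length_days` for analyses that prefer constant-width windows; the
calendar convention is the default because "four months of adherence" is
what a clinic would actually compute. Whether a dispensing made on the VL
day itself should count was genuinely open; excluding the VL day entirely
avoids conditioning the exposure on the outcome visit.

## The four estimators

**Interval gap** is a proportion-of-days-covered (PDC) estimator with
carryover. A supply balance is initialised with the *carry-in*: the days
remaining from the last collection before the window (only the most
recent prior collection date counts, with same-day dispensings pooled;
older unexhausted stockpiles are deliberately ignored). Walking the
window day by day, supply dispensed that day is added first, then one day
of supply is consumed if any is held. Surplus accumulates without cap but
never covers days retroactively. The estimate is covered days over window
days. Capping the within-window stockpile was considered and rejected:
uncapped carryover is the plain reading of "the patient had medication
that day", and the no-retroactive-coverage rule already guarantees that
true gaps are counted.

**Interval average** is medication-possession-ratio (MPR) style
arithmetic: days dispensed in the window, plus the carry-in, minus the
unused tail of the last in-window collection (its days extending past the
window end), over window length. A negative numerator — possible when a
large carry-out follows small in-window supplies — clamps to zero.

**Interval crude** divides the number of refills in the window by the
number of months in it. The default *supply-weighted* mode counts a
collection of *s* days as *s*/30 refills, since clinics issue 60- and
90-day supplies to stable patients and a literal refill count would score
those patients as non-adherent; `event_count` mode preserves the literal
count.

**Overall** adherence divides total days dispensed since second-line
initiation by total days on therapy before the VL.

All four are truncated at 100% after the raw ratio is formed, never at
intermediate quantities; raw values are retained alongside.

Two structural facts about these definitions are worth recording. First,
truncated interval average can never fall below interval gap: every
covered day consumes a unit of dispensed supply, and the only supply the
average method discards (the carry-out of the last in-window collection)
could not have covered in-window days anyway. The test suite checks this
dominance on randomized histories. Second, adding a dispensing event is
*not* universally monotone for interval gap: because carry-in uses only
the last collection before the window, a small collection inserted
between the carry-in source and the window start replaces a larger one
and can lower measured coverage. Monotonicity holds — and is tested —
for events added at or after the window start. This is a real property
of the single-prior-event carry-in rule, not an implementation artefact.

## Cohort filters

Patients pass through four rules in fixed order, each counted once under
the first rule that removes them: (1) ineligible or unusable records
(under 18, missing core fields); (2) switched to second line for reasons
other than first-line virologic failure; (3) any suppressed VL (<400
copies/ml by default; <50 selectable) at least four months after the
switch with zero interval-gap adherence over the preceding four months —
the signature of a patient collecting medication at another site, whose
recorded history is therefore uninformative; (4) no VL at least four
months (inclusive boundary) after the switch. The accounting invariant
`retained + Σ excluded = input` holds on every input and is property-
tested.

Windowed suppression summaries assign a VL with *t* months on therapy to
the six-monthly window *k* ∈ {6, …, 48} when *t* ∈ [k−3, k+3); the
half-open right edge follows from the convention that a 15-month VL
belongs to the 18-month window. When a patient has several VLs in one
window the closest to the target month is used, the earlier date winning
exact ties. "In care" at window *k* means any dispensing or VL at or
after k−3 months; the source databases this emulates do not record formal
disengagement. Printed percentages use half-up rounding
(`floor(100c/n + 0.5)`), the convention clinical tables follow.

## Statistical evaluation

**ROC.** The AUC is computed as the Mann–Whitney concordance probability
with ties counted one half — identical to integrating the empirical ROC
curve — and is checked in the tests against an exhaustive pairwise count.
The 95% interval uses the DeLong asymptotic variance built from mid-rank
placement components; a seeded stratified bootstrap (2000 resamples) is
available via configuration for small or degenerate samples. Single-class
inputs raise an explicit error rather than returning NaN. For the
suppression outcomes the positive class is the suppressed VL; for the
failure outcome (≥1000 copies/ml) the positive class is absence of
failure, so every AUC in a grid is oriented the same way and cells are
comparable. The default comparison outcome is suppression below 400
copies/ml; 50 and 1000 are selectable.

**Dose response.** Observations are binned by adherence
(0–20/20–40/40–60/60–80/80–90/90–100 by default, right-closed only at
100) and the per-bin suppression proportion is reported with the Wilson
95% upper bound. Empty bins are emitted with n = 0 and a null proportion
rather than dropped, because sparse low-adherence strata are themselves a
finding.

**Imputation.** Missing baseline CD4 and log₁₀ VL are filled with the
cohort median (mean selectable) computed over non-missing *patients* —
not observations, which would weight by VL count — and the same value is
reused across all of a patient's observations, with flags recorded.
Square-root CD4 is derived after imputation.

**Regression.** Virologic failure is modelled by maximum-likelihood
logistic regression. Covariates: interval-gap adherence over 4 months per
10 percentage points, time on second line (first year referent), sex
(female referent), age (<26 vs ≥26, older referent), baseline log₁₀ VL,
and square-root baseline CD4 (the square root attenuates the influence
of high counts). Estimates are reported as log-odds with 95% Wald
intervals and a derived odds-ratio column. Univariate fits use one
covariate at a time on the same observation set. Perfect separation and
non-convergence raise a diagnostic error with a ridge
(`fit_regularized`, L2) fallback available; the fallback reports point
estimates without Wald intervals. Reference categories are emitted as
rows without estimates.

## Synthetic cohort generator

The generator emulates the dispensing mechanics the estimators assume:
collections scheduled every 28 days carrying 30 days of medication (the
two-day buffer is what lets the average method overestimate), with stable
suppressed patients occasionally (p = 0.08) issued 60 or 90 days.
Each patient draws a refill-attendance propensity θ from Beta(5, 1.2)
(mean ≈ 0.81); a missed refill delays the collection by 1 + a geometric
gap with mean 21 days. Gaps therefore arise at the collection level —
missed pharmacy visits — not as per-day non-persistence, matching how
dispensing data are actually generated. VLs occur six-monthly with
Gaussian jitter (SD 21 days). Follow-up is log-normal with median 27
months; enrolment is uniform over an eight-year span.

Baselines are calibrated to a typical second-line cohort: CD4 log-normal
with median 174 cells/µL (log-SD 0.672, IQR ≈ 107–265), log₁₀ VL normal
with mean 4.1 (SD 0.815), age log-normal with median 35, 54.4% female,
8.4%/4.7% missingness for baseline CD4/VL. A small fraction (3%) of
patients are "transfers" who collect medication elsewhere: their local
dispensing record is empty while their VLs are usually suppressed,
exercising the zero-adherence exclusion rule. 5% switch for
toxicity/other reasons, exercising the switch-reason filter.

Failure at each VL is Bernoulli with logit-linear risk in the patient's
**true** daily coverage over the preceding four months — computed by the
generator's own possession walk, never by an estimator under evaluation,
which keeps the estimator comparison honest. Covariates are centred at a
reference patient (85% coverage, √CD4 = 13, log₁₀ VL = 4.1, female, 26+,
first year) so the intercept (−2.2 ≈ 10% failure) is interpretable and
slopes are unaffected. Default slopes: −0.7 per 10% coverage, −0.22 per
√CD4 unit, +0.5 per log₁₀ VL, +0.5 after the first year, +0.3 male,
+0.4 age <26. Copies/ml are drawn from log-normal mixtures: log₁₀ ~
N(1.3, 0.5) capped below 400 when suppressed, log₁₀ ~ N(4.2, 0.6)
floored at 1000 when failing; the generator does not produce the
low-level-viraemia band (400–999 copies/ml).

What passing tests on this generator do **not** show about real data: the
generator has no resistance accumulation (failure risk is purely
adherence- and covariate-driven, so discrimination is better than a
clinic would see), no low-level viraemia, no informative loss to
follow-up, no transcription errors in dispensing records, and
conditionally independent outcomes given covariates (so the default
non-clustered standard errors are exactly correct in simulation, which
they need not be in practice).

## Problem sizes and numerical choices

Parameter-recovery checks use 100 replicates of ~400 patients (~2000
observations each), the scale at which Wald intervals are reliable while
the whole suite stays comfortably runnable on a laptop; the estimator-
discrimination check uses 20 replicates of ~1100 patients (~5000
observations). The oracle-equivalence check compares the coverage engine
with an independently coded day-by-day possession oracle on 1000
randomized histories, exactly. The acceptance script uses a 2000-patient
cohort. Default seed for all stochastic procedures is 20141204; every
public stochastic entry point takes an explicit seed.

Degenerate inputs are errors, not silent values: zero-length windows, a
VL dated at or before the switch, single-class ROC inputs, constant
regression outcomes, and all-missing imputation columns all raise with
named messages. Duplicate same-day dispensing rows are merged by summing
days supplied at read time (a patient can collect two months at one
visit), and the metrics pool same-day supplies for carry-in/carry-out so
the two layers agree.

## Known limitations

- The carry-in rule uses only the last collection before the window;
  patients who stockpile across several collections are under-credited.
  This is the intended reading of the interval definitions, not an
  oversight, but it is a modelling choice.
- Calendar-month windows vary in day length (89–124 days for "4
  months"), so the same dispensing pattern can score slightly differently
  depending on the anchor date; the fixed-month-length option trades
  interpretability for constancy.
- The regression treats repeated VLs per patient as independent by
  default; with strong within-patient correlation the naive intervals
  are anti-conservative (the cluster-robust option addresses this).
- Transfers out to other clinics cannot be distinguished from
  disengagement in dispensing data; the in-care definition is
  last-contact-based.
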