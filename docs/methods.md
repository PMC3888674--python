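# Methods

`apcohort` implements a pharmacoepidemiologic cohort analysis of
antipsychotic exposure and cardiac/mortality outcomes on linked
primary-care, hospital-episode and death-registry records.  Because such
record linkages are proprietary, the package ships a synthetic-record
generator with *known* treatment effects and confounding structure; every
downstream stage is validated by recovering that planted truth.  This
note documents the model, the defaults and why they were chosen, the
numerical conventions, and what the simulations do and do not establish.

## Date and calendar conventions

All dates are integer day offsets from a configurable origin (default
2001-01-01); derived window boundaries may be fractional.  Intervals are
half-open `[start, end)`.  One month = 30.4 days, six months = 182.4
days, three weeks = 21 days, one year = 365.25 days.  These constants are
named config values, not magic numbers.

## The synthetic linked records

`synth_ehr` (module `apcohort.synth`) emulates four record streams:
patient registry, antipsychotic prescriptions, coded events (Read-like
primary-care codes, ICD-10-like hospital and death-certificate codes with
admission/discharge dates), and short free-text notes near deaths.

**Population.** Patients register staggered over −3 to +6 years around
the origin; observation runs from `max(registration, origin)` to transfer
out (15% of patients), death, or the ten-year horizon.  Age at origin is
normal (mean 55, SD 20, truncated 18–95), 58% female, matching an adult
primary-care population with the elderly skew of antipsychotic users.
Psychiatric first-record dates are drawn per disease at configurable
prevalences (defaults: depression 10%, dementia 3%, schizophrenia 1.2%,
bipolar 1%).  Binary covariates (diabetes, prior psychiatric admission,
co-medication flags, …) have configurable prevalences; smoking and BMI
carry injected missingness to exercise the missing-indicator machinery.

**Treatment assignment.** Psychiatric patients are treated with base
probability `treatment_given_psych` (default 0.55); a small background
rate (0.02) produces users without a recorded psychiatric code, as in
real primary-care data.  Configured confounders multiply the treatment
*odds* and all outcome *hazards* per carried flag — the mechanism that
plants confounding by indication.

**Prescribing.** Treated patients receive chains of scripts; chain length
is geometric (stop probability 0.08 per script, i.e. about a year of
repeat prescriptions on average), gaps are short (< 30.4 days, 85%) or
long, so episode stitching is genuinely exercised.  Each script draws a
quantity/daily-dose pair and a chlorpromazine-equivalent daily target
from a menu spanning the low/medium/high bands (weighted toward low
doses); the tablet strength is back-computed so the generator knows each
script's true equivalent dose even when fields are later nulled.  A
configurable fraction of users registered before the study window get a
pre-window script, making them prevalent users.

**Outcomes.** Six cause-level processes (sudden cardiac death, other
cardiac death, other death, suicide, coronary heart disease, ventricular
arrhythmia) have piecewise-constant hazards: a baseline rate (defaults on
the scale of published unexposed psychiatric-cohort rates, e.g. all-cause
≈ 26/1000 person-years), multiplied by `true_rr[outcome]` — optionally
further by dose band — while the patient is inside a *current exposure*
window derived from the generator's own scripts with the same 30.4-day
stitching rule the estimator uses, and by the patient's confounder
multipliers.  Event times are drawn by inverse-CDF on the cumulative
piecewise hazard; the earliest death truncates follow-up (no other
competition).  Deaths emit a certificate with a cause code sampled from
the matching code set, sometimes a GP Read code (50%), sometimes a
hospital discharge in the 45 days before death (25%, exercising the
out-of-hospital rule), and usually a free-text note near the death date
containing or omitting trigger strings, with distractor phrases
("motor vehicle accident", "overdose") on non-cardiac deaths.

**What the generator does not model:** real Read/Multilex dictionaries,
depot injections, dose titration within a script, seasonal prescribing,
inter-practice heterogeneity beyond free-text volume, informative
censoring, or frailty.  Passing tests therefore demonstrate that the
pipeline's algebra and estimators are correct under the stated model, not
that the clinical code sets would perform identically on real records.

## Cohorts

Users are indexed at their first in-window script (incident = first
ever; prevalent = earlier use on record) and classified by the first
class prescribed.  Controls (up to 3 per user) match on sex, practice
and birth year within ±2 years, inherit the user's index date (exact
calendar matching; the tolerance is configurable), must have 12 months of
data collection before index, no antipsychotic use on or before index and
no recorded psychiatric disorder; a control later prescribed an
antipsychotic is censored at that script (mirroring the nonuser rule)
rather than excluded, so control person-time is never exposed.  Users
with fewer than 3 eligible candidates keep what exists.  Psychiatric
nonusers are indexed at the first disease record, excluded when treated
before it, censored at any later first script; this cohort is unmatched.
Exclusions (conduction disorder/cardiomyopathy at any time; prior
ventricular arrhythmia, cardioversion, aborted arrest or defibrillator
before registration or index) remove subjects and a removed user's
controls, with a per-rule flow count.

## Exposure

Defined daily dose = prescribed daily dose × tablet strength, converted
to chlorpromazine equivalents per the packaged per-drug table (editable;
the defaults follow widely used consensus equivalents).  Converted values
outside 25–1000 mg, or incomputable ones, are imputed from the median of
calculable values for the drug, then the class, then a package default
(300 mg) — the last resort only matters for degenerate datasets with no
calculable value at all.  Durations (quantity / daily dose) are bounded
to 1–91.4 days with the same two-level imputation (default 28 days).
Both imputations are idempotent: imputed values are always in-range.

Timelines label person-time *current* (script start to 30.4 days after
the expected end, with scripts starting inside that grace period
extending the same interval), *recent* (to 182.4 days after the expected
end) and *past* (until censoring or the next script).  Within current
intervals, sub-segments carry the dose band of the active dose —
overlapping scripts sum; the grace tail carries the most recent script's
dose — and the band of cumulative treated (current) time (<1, 1–3,
>3 years).  The timeline partitions `[first script, censor)` exactly; an
independent day-by-day scanner in the test suite checks state and dose
band per day on random prescription sets.

## Outcome adjudication

Source precedence: death certificate, then free text, then Read code.
Dates: certificate → recorded death date; free text → min(death date,
note date); Read code → min(death date, code date); both free text and
code → the earlier.  All-cause mortality excludes suicide-coded deaths
(which still end follow-up).  The three sudden-cardiac-death tiers are:
narrow code set with an out-of-hospital requirement (no discharge within
30 days before death, no death during an admission); broad code set with
a hospitalisation exclusion (same 30-day window by default; an
"any hospitalisation on record" reading is available because the source
phrasing is ambiguous); and the broad set restricted to the primary-care
record (codes and free text only).  The broad set is constructed as a
superset of the narrow set so the tiers nest by code.  Death-linked Read
codes are accepted within ±21 days of death — the same three-week window
as the free-text search, chosen because no separate window is stated.

Free-text search is literal and case-insensitive: trigger substrings and
two conjunctive pairs, restricted to notes within ±3 weeks of death, to
practices with above-median free-text volume per patient, and to dates
after a configurable start year (default 2006); the verdict is SCD unless
an exclusion phrase appears within 500 characters either side of the hit.
The exclusion-phrase list replaces a human review panel and is packaged
as an editable config; tests check rule faithfulness (perfect recall of
trigger-bearing notes, exclusion phrases always vetoing), not clinical
accuracy.

## Rates and regression

Follow-up runs from index to the first of event, death, transfer, or end
of collection; users contribute only current-exposure person-time to the
primary comparisons (configurable).  Segments split at exposure-state
changes, dose changes, cumulative-duration crossings and age-band
birthdays (18–29/30–64/65–79/80+); the event joins the segment active on
its day.  Rates are per 1000 person-years.

Rate ratios come from a Poisson GLM for event counts with log
person-time offset (statsmodels IRLS, deviance tolerance 1e-8, ≤ 100
iterations), Wald 95% CIs on the log scale.  Age band and sex (and the
exposure factor) are forced; full adjustment first truncates the
alphabetical candidate pool so non-intercept parameters stay within
events/5, then removes candidates block-wise (joint Wald tests for
categorical covariates) while any has P ≥ 0.10, and finally while any
has P ≥ 0.05 — the backward realisation of the enter-0.05/remove-0.10
rule.  BMI enters as bands with an explicit "missing" level, smoking as
categories including "missing" (the missing-indicator method; no
imputation of covariates).  Comparisons with zero events in a level are
reported "NC" rather than raising.  Aggregating segments to covariate
cells before fitting leaves the point estimates unchanged for this model
family (sufficient statistics are cell sums); the implementation fits on
aggregated cells for speed.

## Hazard smoothing

Follow-up from treatment start is divided into 100 equal periods;
events/person-time per period are occurrence–exposure rates, i.e. the
increments of a Nelson–Aalen-type estimator on a person-time grid.  The
smoothed curve is a kernel-weighted average of those increments
(Epanechnikov default; weights normalised to unit mass, so a flat grid
returns exactly its constant), with pointwise variance Σw²·d/PT² and a
log-scale normal CI.  The default bandwidth is five grid periods; points
within one bandwidth of either end are flagged as boundary estimates (no
boundary correction is attempted).  The ratio curve divides two smoothed
curves pointwise, combines variances on the log scale, and masks points
where either curve is zero.  The curve comparing atypical to typical
initiators is computed on the whole user cohorts (a matched-restriction
variant can be built from the same pieces).

## Validation experiments and their problem sizes

The acceptance suite exercises: exact day-level agreement of the
timeline algebra on 1000 random prescription sets; person-time
conservation on a 10 000-patient cohort; closed-form agreement of the
crude rate ratio on 100 random two-cell tables; 95% CI coverage of unity
across 200 null replicates at n = 20 000; recovery of planted rate
ratios 0.5/2/4 at n = 50 000 under a planted confounder, averaging six
independent replicates per value so Monte-Carlo error (~0.02 on the log
scale) does not dominate the bias bound; monotone dose-band recovery in
50 replicates at n = 30 000; thirty handcrafted adjudication cases with
exact expected labels; constant-hazard recovery at n = 50 000; and the
five-events-per-parameter budget plus noise-covariate retention over 100
selection replicates.  The recovery and dose designs raise the unexposed
mortality to ≈ 93/1000 person-years, lengthen prescribing chains, and
(for recovery) disable field missingness and strengthen the confounder
(prevalence 0.25, odds ×5, hazard ×3): a priori power calculations put
the per-band/per-arm event counts where the planted orderings are
detectable at ≥ 3 standard errors, so the pass criteria test
correctness, not luck.

## Known limitations

* The rule-based free-text verdict stands in for human expert review;
  concordance statistics of a review panel are out of scope.
* No propensity-score matching, Cox modelling, overdispersion correction
  (a robust-variance option exists but is off by default), or
  multiple imputation.
* Chlorpromazine-equivalence factors are consensus approximations; users
  with a preferred equivalence standard should override the table.
* The simulator's hazards are piecewise-constant and person-level
  (no frailty), which is exactly the model the Poisson estimator
  assumes; real-data robustness is not established here.
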