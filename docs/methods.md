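# Methods

## Episode model

The unit of analysis is the admission episode: the continuous period from
admission to a psychiatric ward (from the community or from a general ward)
to discharge to the community, transfer to a general ward, or death in the
ward. Claims record stays per hospital, so an episode with an
inter-hospital transfer is fragmented into consecutive stay rows. Linkage
chains two stays of one patient when the next admit date is at most
`gap_days` after the previous discharge date. The default `gap_days=1`
treats same-day and next-day readmission as a transfer: claims encode
transfers as a discharge plus an immediate admission, and a one-day
tolerance absorbs boundary conventions. Chaining is purely date-based; the
`other_hospital` destination code is not required, but a chain that *ends*
on `other_hospital` is rejected as structurally invalid. Episode
attributes (fee type, admitting hospital and its prefecture, legal admission
type, demographics) come from the first segment; the transfer flag is set
when an episode spans two or more hospitals. A patient may contribute
several episodes; the admission, not the patient, is the analysis unit, so
readmission correlation is out of scope.

Event time is `end date − admission date` in days, floored at one day so
same-day discharges get a positive survival time. Follow-up is
administratively censored at the earlier of the observation boundary
(default 2016-09-30) and `max_days=365` after admission; an event on the
boundary day counts as an event. "Within 90 days" is evaluated inclusively:
the curves are right-continuous, so the value at day 90 includes day-90
events.

Cohort rules are applied in order — window, enrollment, identification
errors — and each episode is logged under the first rule it fails, so the
exclusion log always sums to the input count:

1. episodes admitted before the window start are *prevalent* if still in
   the ward at the window start, otherwise *out of window* (the latter
   category exists so accounting stays exact for arbitrary inputs);
2. enrollment is verified by an enrollment marker in a month strictly
   before the admission month or any claim dated strictly before the
   admission date — a literal reading of "enrolled at least one day before
   admission" at the monthly granularity of claims;
3. a patient with two strictly overlapping stays at different hospitals is
   removed with all of their episodes. Boundary contact (discharge day =
   next admit day elsewhere) is the legitimate transfer pattern and never
   counts. Merged identities whose stay histories happen to interleave
   without overlap are undetectable, as in real claims.

Planned admissions are operationally defined as electroconvulsive therapy
anywhere in the episode with a total stay of at most 3 days; all other
episodes carry the legal voluntary/involuntary flag. Route is
`general_ward` when a general-ward stay of the patient ends on the
admission date or the day before.

## Competing-risks estimation

The Aalen-Johansen estimator is implemented directly (see the formulas in
the README). Ties at one time are processed jointly and events precede
censorings in risk-set accounting. The identity Σ_k CIF_k + S = 1 holds at
every step by construction and is asserted to 1e-10 in tests. An optional
Aalen-type pointwise variance is provided (Marubini–Valsecchi form,
computed with cumulative sums); it is used to set Monte-Carlo tolerances
where censoring inflates the binomial standard error. With no censoring
the estimator reduces to the empirical sub-distribution function, and with
a single cause to 1 − Kaplan-Meier; both identities are property-tested,
and the implementation is cross-checked against lifelines'
`AalenJohansenFitter` on tie-free data.

## Length-of-stay model and calibration

Latent event times follow piecewise-constant cause-specific daily hazards
on [0, 90), [90, 180), [180, 270), [270, ∞) days — a change-point structure
matching the segmented discharge pattern of acute units, whose discharge
intensity drops after the 90-day certification horizon. For constant
hazards the cumulative incidence gained by cause k over an interval is
`(h_k/H) · S(start) · (1 − exp(−H·Δt))`, which gives both an exact
closed-form CIF and an exact interval-by-interval inversion: given target
CIF values per cause at 90/180/270/360 days, the all-cause increment fixes
H on each interval and the cause split fixes each h_k. `calibrate_hazards`
therefore reproduces any feasible target profile to floating-point
round-off (no iterative root-finding is needed). Infeasible targets —
decreasing, or demanding more mass than survives into an interval — raise a
configuration error.

Default per-unit-type community profiles are the national per-fee-type
cumulative incidence table; the overall profile pins 64.1%/85.7% at 90/360
days with 180/270-day values (79.2, 83.5) taken as the admission-weighted
aggregate of the per-type profiles. Competing-event profiles are only
published for the whole population (0.3% general-ward transfer and 3.1%
death at 360 days), so per-type competing profiles are imputed by scaling
the overall profile in proportion to each type's residual non-community
mass at 360 days. This keeps calibration feasible for high-discharge units
(a 98.7% community incidence leaves under 1.3% for competing causes) and
gives plausibly elevated death incidence in dementia-care units
(~6.9% at 360 days).

## Synthetic claims generator

The generator's defaults encode the study conditions: two fiscal years of
admissions (2014-04-01..2016-03-31) observed to 2016-09-30, the national
fee-type mix, 2.6% transfer prevalence, admission-type shares
64.4/35.1/0.5, route shares 85.3/14.7, sex/age/diagnosis margins, and a
July-peaked log-linear seasonal intensity
`exp(amplitude · cos(2π(m − peak)/12))` with amplitude 0.1 — a relative
summer elevation of roughly e^0.2 ≈ 22% peak-to-trough, consistent with a
visually evident but moderate seasonal swing. Monthly intensity is
weighted by month length; admission day is uniform within month. Each
stochastic concern (dates, attributes, event times, transfers, planned
marking, withholding, prevalence, hospital assignment) uses its own named
random stream derived from the seed, so toggling one feature leaves the
others' draws unchanged; identical configs and seeds give byte-identical
outputs.

Two calibration-preserving constructions deserve note:

* **Transfers.** One-day stays cannot contain a transfer, which would
  deflate realised prevalence below `transfer_prob`; the assignment
  probability is inflated by 1/P(stay ≥ 2 days) (closed form) so the
  realised prevalence is unbiased. The transfer day is uniform on
  [1, stay − 1] — the true within-episode timing distribution is unknown,
  so the generator exposes it rather than asserting one. Transfers
  scheduled beyond the observation boundary are never emitted; the
  resulting undercount of the transfer flag is of order
  `transfer_prob × P(open at boundary) × P(transfer past boundary)` ≈ 0.01
  percentage points, far below sampling noise at the default sizes.
* **Planned admissions.** Rather than forcing short stays (which would
  bias the event-time law), the generator marks electroconvulsive therapy
  among episodes whose hazard-drawn stay is already ≤ 3 days, with
  probability `planned_share / P(stay ≤ 3)` per fee type. The classifier
  then recovers the planned share in expectation and the event-time
  distribution remains exactly the calibrated one. A small ECT rate among
  longer stays (default 1%) exercises the rule's negative branch.

Fragmentation emits k+1 stay rows for an episode with k transfers, dates
meeting on the transfer day, destination `other_hospital` on all but the
last segment; stays open at the observation boundary have no discharge date
and no destination. Each hospital hosts one unit type (pools allocated
proportionally to the admission mix) and belongs to one prefecture
(round-robin). A `public_fund_frac` share of episodes is withheld to
emulate publicly funded claims missing from the database — default 0, so
the episode-vs-single-hospital comparison isolates the definitional effect;
tests exercise the documented 19% setting. Prevalent patients (default 5%
of the cohort size, a value chosen to exercise the filter without dominating
the input) are admitted 1–180 days before the window start with their
remaining stay shifted so the stay straddles the window start. Enrollment
markers cover the two months before each patient's first admission.
`inject_id_errors` merges a sampled fraction of patient ids into another
patient's id to create the overlapping-stay signature the filters must
catch.

### What the generator does and does not emulate

It reproduces the structural features the pipeline consumes: stay-level
fragmentation with monthly enrollment semantics, competing discharge
destinations with change-point hazards, seasonal admission intensity, a
missing subpopulation, and prevalent patients. It does not model billing
lines or amounts, drug or procedure claims, correlated readmissions of one
patient, insurance-id changes over time, case-mix differences between
hospitals beyond the unit type (within a type, hospitals differ only by
sampling noise), or survey non-response. Passing round-trip tests
therefore shows the pipeline is correct under the stated claim structure,
not that real-data idiosyncrasies beyond that structure are handled.

## Seasonal model

The monthly admission counts are fitted with a log-linear Poisson model
with intercept, centred linear trend (per year) and the first seasonal
harmonic in calendar month, by iteratively reweighted least squares
(relative deviance change below 1e-10 with a +0.1 offset so perfect fits
converge; at most 100 iterations; non-convergence raises an error carrying
the deviance trace). The fit is summarised by the harmonic amplitude
√(a²+b²) on the log scale and the calendar month maximising
a·sin + b·cos. This model is a deliberately simple stand-in for smooth
trend models of monthly counts: it is implementable, testable (matched
against an independent GLM fit and a direct numerical optimum to 1e-8 in
log-likelihood), and captures the summer-peak question; no equivalence with
spline-based smoothers is claimed.

## Hospital-level rates and concordance

Hospital-level "discharge rate within 90 days" is the crude proportion of
the hospital's episodes discharged to the community within the horizon, not
an Aalen-Johansen estimate: published rank-group ranges that include exact
0.0 and 100.0 endpoints indicate simple proportions, and competing events
are rare at 90 days (the divergence between the two definitions grows with
the censoring and competing-event shares, so the estimator choice is a
documented, configurable risk). Hospitals with fewer than 10 episodes are
excluded; eligible hospitals are sorted by rate with ties broken by
hospital id, then cut into 5 groups (≥ 20 hospitals) or 3 (< 20), group
sizes differing by at most one with remainders assigned to the
lowest-ranked groups — a deterministic, order-free rule.

The single-hospital view chains stays within patient × hospital under the
same gap rule; every chain is one pseudo-admission, a transfer out is not a
community discharge, and follow-up knowledge ends with the hospital's own
records (transferred-out patients count in the denominator as
not-discharged; a flag could alternatively exclude them, but including them
mirrors a census form filled from hospital records). Prefecture indicators
are admission counts (overall, by age, by diagnosis) and the 1-year
community-discharge proportion — Aalen-Johansen at 360 days in episode
mode, the crude within-hospital proportion in single-hospital mode. With
transfers present the single-hospital definition necessarily counts more
admissions and a lower discharge proportion; the package asserts the
direction, not the magnitude, which depends on transfer prevalence and the
coverage gap.

## Problem sizes and numerical choices

Validation runs use 50,000 episodes for national quantities (Monte-Carlo
SE ≈ 0.2 percentage points at p ≈ 0.64) and 12,000 per stratum for
fee-type-specific quantities, sizes at which sampling error is well below
the differences of interest while the full suite runs in seconds.
Recovery tolerances are 3 estimated standard errors (the Aalen variance
where administrative censoring inflates the binomial SE), and 99%
binomial intervals for classified shares; marginal checks across many
levels jointly use the 99.9% quantile to control family-wise error.
Degenerate inputs are defined errors: empty survival samples, all-zero or
short monthly series, constant vectors in correlations, decreasing or
infeasible calibration targets, probability vectors off unit sum
(tolerance 1e-9).
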