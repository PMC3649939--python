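# Methods

This note documents the statistical models, numerical choices and design
decisions behind `npccdb`, and what the synthetic cohorts do and do not
emulate.

## Data model

Registry records are kept in decimal years (0.1-y resolution; the source
data report years to one decimal). No calendar dates are modelled — every
within-disease analysis works in time relative to *neurological onset*,
the age at the first reported neurological sign. Symptoms are recorded by
first manifestation only and persist thereafter; no remission or
within-symptom worsening is modelled. Patients diagnosed before any
neurological sign carry no onset age and are excluded from
onset-normalised analyses rather than imputed.

The shipped symptom catalog holds 72 neuropsychiatric signs plus visceral
items. Signs named in the published cohort descriptions carry the
reported prevalences and Kaplan-Meier onset medians; the remainder of the
72-sign inventory is not public, so those entries are explicit placeholder
reconstructions (`np_sign_NN`). Severity weights use a three-tier scheme
(1 mild / 2 moderate / 4 severe); the catalog is configuration, so a
verbatim scoring rubric can replace it. Hearing/auditory items are
excluded from the default inventory. The screening-index rubric shipped
for tests is likewise a small synthetic stand-in (thresholds 40/70 are the
published category cut points; the published item weights are treated as
user-supplied configuration).

## Cumulative severity score

`S(t) = Σ_s w_s · 1[onset_s ≤ t]` over catalog symptoms; the *cleaned*
variant drops seizure-domain symptoms. The score is additive over any
partition of the catalog, monotone in `t`, and the cleaned variant is
dominated by the raw one with equality exactly until the first
seizure-domain manifestation — these are tested as invariants. Events
whose symptom id is absent from the catalog in use contribute nothing,
which is what makes sub-catalog additivity exact. Grid trajectories
default to annual steps spanning `[0, last_visit − onset]`.

## Survival layer

Kaplan-Meier from first principles: at each distinct event time,
`Ŝ` multiplies `1 − d_i/n_i`; subjects censored at an event time remain in
that risk set (events precede censorings at ties — the standard
convention; the source is silent). Variance is Greenwood's; pointwise CIs
use the log(−log) transform to stay inside [0, 1]; the median is the
smallest event time with `Ŝ ≤ ½`; its 95% CI inverts the transformed
pointwise bands (Brookmeyer-Crowley). All-censored input is a valid flat
curve with undefined median, not an error. Symptom onsets recorded before
neurological onset are clamped to zero with a logged warning. Symptom
ranking sorts by KM median (undefined last), ties broken by frequency
descending, then id — a deterministic total order.

One stated invariant was corrected during implementation: *adding* a
censored observation beyond the last event time does change earlier
survival values (it enlarges every risk set); what is invariant is the
*location* of such a censoring beyond the last event. The test suite
asserts the corrected form.

## Progression classification

Two-segment joined least squares `y = β0 + β1 t + β2 (t−c)+`, exhaustively
over grid candidates `c` with at least 3 points per segment (trajectories
have ≤ ~45 annual points, so exhaustive search avoids convergence
questions); ties in SSE resolve to the earliest candidate. A trajectory is

* **fulminant** if every annual score from year 1 on strictly exceeds the
  cohort mean at that year (≥ 3 comparable years required; year 0 is
  excluded because scores there are zero by construction under onset
  normalisation),
* else **accelerated** if slope_post/slope_pre ≥ 2, the breakpoint is
  ≥ 2 y after onset, and the two-segment fit beats the single line at
  α = 0.05 with an F-criterion on (1, n−4) degrees of freedom,
* else **steady**; trajectories shorter than 6 annual points are
  *insufficient data*.

Labels are invariant under common rescaling of all severity weights (every
decision depends on ratios or on comparisons of identically rescaled
quantities); the tests verify exact label equality under a power-of-two
rescaling.

The cohort envelope (mean ± SD per grid year, over trajectories still
under follow-up) retains years covered by at least 20% of trajectories
(minimum 2), so the sparse late tail does not dominate the trend fit. The
trend is an OLS of the envelope mean on time; for a constant response the
R² is defined as 0.

**Acceleration-factor statistic.** The per-patient slope ratio divides two
noisy OLS slopes and is heavy-right-tailed (occasional near-zero
pre-slopes), so its arithmetic mean over patients is unstable. The
cohort-level acceleration factor is therefore reported as the ratio of
mean slopes, `mean(slope_post)/mean(slope_pre)`, over latent accelerated
patients; per-patient ratios are still reported in the calls table.

## Exact tests

`fisher_exact` enumerates the hypergeometric distribution of the first
cell with margins fixed, in exact integer arithmetic: the two-sided p sums
the probabilities of all tables whose probability is at most that of the
observed table, with 1e-7 *relative* slack for tie semantics (applied as
an integer inequality, so the computation stays exact at any table size).
Degenerate margins give p = 1. The tests check full-enumeration rational
oracles exhaustively (all tables with total ≤ 30) and cross-check
`scipy.stats.fisher_exact`.

**Seizure window procedure.** For each patient with a first seizure and
≥ 2 y of follow-up on both sides, the seizure-cleaned score increments
over the two years before and after the seizure are compared; the patient
is flagged accelerated when `Δpost / max(Δpre, ε) ≥ 2` with ε equal to
half the smallest catalog weight (so a flat pre-window cannot divide by
zero). Each seizure-free patient is evaluated at a matched onset-relative
time drawn (seeded) from the seizure times compatible with that patient's
follow-up — the source gives no matching rule, so the pairing is explicit,
random and reproducible. The resulting 2×2 (seizure × flag) table goes to
the Fisher test. The dichotomisation rule itself (threshold 2, window
2 y) is configuration.

**Screening-index sensitivity vs duration** stratifies patients at < 3 y
vs ≥ 3 y of neurological disease at diagnosis against the *likely*
category (boundaries: `total ≥ 70` likely, `40 ≤ total < 70` follow-up).

**Oxysterol correlation** averages up to three samples per patient (levels
and scores at the sampling ages) and regresses mean level on mean score
per analyte; samples below the screening cut-offs (24.5 ng/mL triol,
47.5 ng/mL 7-ketocholesterol) are flagged.

## Reporting

Integer percentages round halves away from zero, implemented in integer
arithmetic (`(200n + d) // 2d`); the convention is fixed by the printed
pair 62/80 → 78%. Two published figures (30/42 → "70%", 5/42 → "13%")
are inconsistent with any single rounding rule and are treated as
manuscript rounding slips — they are not machine-checked. Filipin
percentages use the tested subset as denominator; allele-type percentages
use the total mutant-allele tally, which may be supplied at cohort level
because the published allele total (80) exceeds what the per-patient
identified-allele counts can reach (77) — an inconsistency of the source
counts that the reference fixture reproduces rather than repairs.

## Synthetic cohort generator

The generator's defaults are the study conditions of the published
42-patient German-Swiss cohort; every mechanism is seeded and recorded in
provenance for truth-recovery tests.

* **Onset ages**: truncated normal on [0, ∞) whose *truncated* mean/SD
  equal the configured 7.9/6.9 y (the published values are observed
  moments), parent parameters solved numerically.
* **Diagnostic delay**: log-normal moment-matched to 5.7/7.6 y. A
  truncated normal cannot reach the observed coefficient of variation
  (1.33 > 1), so the delay family is right-skewed by necessity as well as
  realism. A configured fraction (4/42) of patients is diagnosed before
  any neurological sign and carries no onset age. Follow-up ends uniform
  1-10 y after diagnosis.
* **Symptom onsets**: each symptom manifests with its prevalence (a cure
  fraction); conditional onsets are log-normal (support > 0, right-skewed,
  σ = 0.5 by default). Because of the cure fraction, the cohort-level KM
  median is *not* the conditional median; for signs whose configured
  median is a published KM median, the log-normal location is calibrated
  numerically (Brent root-finding over a quadrature over the archetype
  mixture) so that the marginal survival function crosses ½ exactly at the
  configured value. Placeholder signs use the conditional-median
  convention, with onset medians and prevalences designed so the latent
  expected score accumulates near-linearly over the first three disease
  decades — emulating the near-linear mean progression that registry
  cohorts report.
* **Archetypes** (steady 24/37, fulminant 7/37, accelerated 6/37 among
  neurological patients): steady uses the latent timeline unchanged;
  fulminant compresses it twofold (uniformly faster accumulation);
  accelerated patients draw a breakpoint `b` (normal 6.7/2.5 y truncated
  to [4, 12] for pre-segment identifiability) and a ratio `r` (normal
  2.9/1.1 truncated symmetrically to [1.8, 4.0], which keeps the realized
  mean at the configured 2.9 while excluding ratios indistinguishable from
  steady). After `b`, arrivals are scheduled in *expected-score space*:
  a latent onset `u > b` maps to `b + (C(u) − C(b)) / (r · C′(b))`, where
  `C` is the expected latent score curve — so the expected post-breakpoint
  slope is exactly `r` times the local slope at the breakpoint, wherever
  `b` falls on the disease course. Post-breakpoint follow-up is uniform
  3-6 y: an accelerated course is an *observed* phenotype (the breakpoint
  must lie within follow-up) and a multi-fold decline curtails further
  follow-up.
* **Seizures**: prevalence 0.35 at cohort level, realised among
  neurological patients at 0.35/(1 − frac_pre_neuro). With probability
  4/6 an accelerated patient's first seizure falls uniformly in the year
  before the breakpoint; all other seizures draw from a background
  log-normal truncated within follow-up (prevalence is an observed-cohort
  statistic, so times are drawn conditionally on occurring during
  follow-up). A null mode assigns all seizures independently of the
  archetype for type-I-error studies.
* **Diagnostic work-up, visceral history, alleles, oxysterols**: Bernoulli
  fields matching the published marginals (filipin 26/42 tested with
  17:8:1 classic:variant:indifferent, 36/42 with both alleles, allele
  types 62:2:5:9:2, splenomegaly 38/42, jaundice 18/42, organomegaly
  9/42); screening-index answers are derived mechanistically from the
  symptoms present at diagnosis plus visceral history — which *generates*
  the negative correlation between screening sensitivity and disease
  duration rather than hard-coding it. Oxysterol levels are linear in the
  concurrent score (triol 29 + 2.0·score ± 10; 7-KC 78 + 5.0·score ± 20),
  placing all draws above the screening cut-offs with the published
  starting ranges.

### What the generator does not emulate

* The observed association between fulminant course and early onset age
  (onset ages are drawn identically across archetypes; biasing fulminant
  onsets early would shift the cohort onset mean off its configured
  value).
* Correlations between symptom onsets within a patient beyond the shared
  archetype warp; real patients likely have correlated domains.
* Informative censoring other than the curtailed post-breakpoint
  follow-up of accelerated patients (a mild, documented violation of
  independent censoring).
* The real 72-sign inventory: placeholder identities, prevalences and
  onset medians are statistical filler, so analyses keyed to placeholder
  *identities* say nothing about real data. Passing recovery tests show
  the *pipeline* recovers what the generator encodes — not that the
  generator matches reality beyond the published marginals it was built
  from.
* The truncation of the acceleration-ratio draw shrinks its SD below the
  configured 1.1 (≈ 0.6); the mean is preserved exactly.

## Problem sizes and tolerances

Recovery tests run at n = 500 (pipeline closure; KM-median tolerances
0.5/0.5/1.0 y ≈ 3 Monte-Carlo standard errors of the respective medians)
and n = 1000 (generator moments; tolerances from binomial/normal standard
errors as stated in each test). Type-I behaviour of the seizure test uses
100 null cohorts of n = 150. The changepoint study uses 100 noisy
replicates (σ = 0.5) of a slope-1→3 trajectory with breakpoint 6 y.
Exact-arithmetic oracles cover all 2×2 tables with total ≤ 30
(exhaustive) and 1,000 randomised small survival datasets. Age
comparisons carry a 1e-6…1e-9 y slack; SSE ties in the changepoint search
resolve at 1e-12.
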