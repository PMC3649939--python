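# npccdb

Natural-history analysis toolkit for **Niemann-Pick disease type C (NP-C)**
registry cohorts.

NP-C is a rare, progressive lysosomal storage disorder (NPC1/NPC2,
autosomal-recessive) whose broad spectrum of visceral, neurological and
psychiatric signs delays diagnosis by years. Registry studies address this
by reconstructing, per patient, *when* each of ~72 neuropsychiatric signs
first manifested relative to neurological disease onset. This package
implements that analysis stack for registry-style longitudinal records —
and, because raw patient-level registry data are not public, ships a
calibrated synthetic cohort generator so every analysis runs and is tested
end-to-end without real patient data. It is aimed at biostatisticians and
clinical researchers modelling rare-disease natural history.

## The methods at its core

**Cumulative severity-weighted outcome score.** A patient's score at time
*t* (years after neurological onset) is the sum over all catalog symptoms
that have manifested by *t*:

    S(t) = Σ_s  w_s · 1[ onset_s ≤ t ],   w_s > 0,

each symptom contributing once, at first manifestation, and persisting.
A *cleaned* variant excludes seizure-domain symptoms so progression around
a first seizure can be measured without the seizure's own points.

**Censored time-to-symptom estimation.** Each symptom's manifestation is a
time-to-event outcome; patients not (yet) showing it are censored at last
visit. The survival function is the Kaplan-Meier product-limit
Ŝ(t) = Π_{t_i ≤ t} (1 − d_i/n_i) with Greenwood variance, median defined
as the smallest event time with Ŝ ≤ ½, and a Brookmeyer-Crowley 95% CI
for the median (implemented from first principles; `lifelines` serves as
an independent cross-check in the tests).

**Progression phenotypes.** Annual score trajectories are classified as
*steady*, *fulminant* (every annual score strictly above the cohort mean),
or *accelerated* — an initially steady course whose slope later increases
severalfold, detected by exhaustive two-segment joined least squares
(`y = β0 + β1 t + β2 (t − c)+` over candidate breakpoints `c`), accepted
when the post/pre slope ratio reaches 2, the breakpoint lies ≥ 2 y after
onset, and an F-criterion prefers two segments over one line.

**Exact association tests.** 2×2 contingency tables (seizure status ×
subsequent acceleration; screening-index category × disease duration) are
tested with a two-sided Fisher exact test computed by exact integer
hypergeometric enumeration.

## Worked example

```sh
python analysis/01_simulate_cohort.py          # write results/cohort/
python analysis/02_symptom_survival.py         # KM onset ranking
python analysis/03_progression.py              # trend + progression calls
python analysis/04_associations.py             # Fisher tests + oxysterols
python analysis/05_cohort_summary.py           # diagnostic-findings summaries
```

Step 01 prints the simulated study conditions (n = 500, seed 1234):

    neurological onset: mean 7.9 y, sd 6.9 y
    diagnostic delay:   mean 5.7 y, sd 7.4 y
    seizure prevalence: 0.32
    archetypes: {'steady': 286, 'fulminant': 91, 'accelerated': 63, 'pre_neurological': 60}

Step 02 recovers the configured onset sequence — less specific
cognition/coordination deficits precede the classical signs by years:

    impaired_fine_motor_skills  km_median 3.2   frequency 0.75
    cognitive_impairment        km_median 3.3   frequency 0.82
    clumsiness                  km_median 3.7   frequency 0.77
    ...
    vsgp                        km_median 7.2
    ataxia                      km_median 7.0

Step 03 fits the near-linear cohort trend and recovers the latent
progression archetypes:

    cohort trend: score = 3.65 * t + -0.35  (R^2 = 0.996)
    accelerated recall: 0.92 (n=63)

Step 04 runs the seizure-acceleration Fisher test. In the default mixture
only ~2/3 of the ~16% accelerated patients carry a breakpoint-linked
seizure, so a single cohort draw can fall short of significance (here
p = 0.21); under the linkage-enriched configuration the association is
unambiguous (p = 2.6e-06). The screening-index sensitivity falls sharply
for short disease duration (p = 1.3e-50), and mean plasma
cholestane-3β,5α,6β-triol tracks the mean score with the configured slope
(2.0, R² = 0.97).

Step 05 reproduces the published diagnostic marginals from the shipped
synthetic reference cohort (n = 42): filipin 65%/31% classic/variant of
tested, 86% with both alleles identified, 78% missense alleles, 43%
neonatal jaundice, 21% isolated organomegaly, 90% splenomegaly, 17%
screening-index follow-up.

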