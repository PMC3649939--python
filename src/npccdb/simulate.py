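"""Seeded synthetic registry cohorts with the statistical structure the
downstream analyses assume.

The generator emulates a rare-disease natural-history cohort: neurological
onset ages (truncated normal whose *observed* moments match the configured
mean/SD), a right-skewed diagnostic delay (log-normal, moment-matched — a
truncated normal cannot reach the observed coefficient of variation), a
small fraction diagnosed before any neurological sign, per-symptom
manifestation prevalences with log-normal onset offsets, three latent
progression archetypes (steady / fulminant / late-accelerated), and
seizures that, for most accelerated patients, strike in the year before
the acceleration breakpoint.

Because a symptom manifests only with its prevalence (a cure fraction),
the marginal survival function is ``S(t) = 1 - prevalence * F(t)`` and the
cohort-level Kaplan-Meier median is *not* the conditional onset median.
The generator therefore calibrates each symptom's log-normal location
numerically so that the archetype-mixture marginal survival crosses 1/2
exactly at the configured median offset — i.e. the configured values are
recovered by the survival pipeline, not merely plugged into a conditional
distribution.  For prevalences <= 0.5 the KM median is undefined and the
conditional-median convention is used instead.

All randomness flows through one ``numpy`` Generator in a fixed order
(patient by patient, symptoms in sorted-id order), so a given seed and
configuration reproduce a byte-identical cohort.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq, root
from scipy.special import ndtr, ndtri

from .catalog_default import default_catalog, default_rubric, default_symptom_params
from .model import (
    AlleleType,
    Cohort,
    FilipinPattern,
    OxysterolSample,
    PatientRecord,
    RiskIndexRubric,
    Sex,
    SymptomCatalog,
    SymptomEvent,
)

ARCHETYPES = ("steady", "fulminant", "accelerated")


class SymptomParams(BaseModel):
    prevalence: float = Field(ge=0.0, le=1.0)
    median_offset: float = Field(gt=0.0)
    sigma: float = Field(default=0.5, gt=0.0)
    #: True: median_offset is a cohort-level (censored, KM) median and the
    #: latent location is calibrated so the pipeline recovers it; False:
    #: median_offset is the conditional onset median among manifesting
    #: patients (used for reconstructed signs without published KM medians)
    median_is_km: bool = True


class GeneratorConfig(BaseModel):
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the published cohort statistics: onset 7.9 +/- 6.9 y,
    diagnostic delay 5.7 +/- 7.6 y, 4/42 diagnosed pre-neurologically,
    progression mix 24:7:6 over 37 classified patients, ~2.9 +/- 1.1-fold
    late acceleration with breakpoint 6.7 +/- 2.5 y after onset, and 35%
    seizure prevalence with seizures preceding the acceleration in 4 of 6
    accelerated patients.
    """

    n_patients: int = Field(default=42, ge=1)
    seed: int = 0

    neuro_onset_mean: float = 7.9
    neuro_onset_sd: float = Field(default=6.9, ge=0)
    diag_delay_mean: float = 5.7
    diag_delay_sd: float = Field(default=7.6, ge=0)
    frac_pre_neuro_diagnosis: float = Field(default=4 / 42, ge=0, le=1)

    #: per-symptom (prevalence, median onset offset, log-sd); defaults to
    #: the shipped catalog's parameters
    symptom_params: Optional[dict[str, SymptomParams]] = None

    progression_mix: tuple[float, float, float] = (24 / 37, 7 / 37, 6 / 37)
    accel_ratio_mean: float = 2.9
    accel_ratio_sd: float = Field(default=1.1, ge=0)
    #: symmetric truncation about the mean: keeps the realized archetype
    #: mean at the configured value while excluding ratios too close to 1
    #: to constitute an accelerated course
    accel_ratio_bounds: tuple[float, float] = (1.8, 4.0)
    accel_delay_mean: float = 6.7
    accel_delay_sd: float = Field(default=2.5, ge=0)
    accel_delay_bounds: tuple[float, float] = (4.0, 12.0)
    #: follow-up beyond the breakpoint, uniform on these bounds: an
    #: accelerated course is an observed phenotype (breakpoints must lie
    #: within follow-up) and a multi-fold decline curtails further follow-up
    post_breakpoint_followup: tuple[float, float] = (3.0, 6.0)
    fulminant_speedup: float = Field(default=2.0, gt=0)

    seizure_prevalence: float = Field(default=0.35, ge=0, le=1)
    #: probability that an accelerated patient's first seizure falls in the
    #: year preceding the breakpoint
    accel_seizure_prob: float = Field(default=4 / 6, ge=0, le=1)
    #: False = null mode: seizures assigned independently of archetype
    seizure_linked_to_acceleration: bool = True
    seizure_bg_median: float = 8.0
    seizure_bg_sigma: float = 0.6

    followup_min: float = Field(default=1.0, gt=0)
    followup_max: float = Field(default=10.0, gt=0)
    frac_deceased: float = Field(default=8 / 42, ge=0, le=1)

    # diagnostic-workup marginals
    frac_filipin_tested: float = Field(default=26 / 42, ge=0, le=1)
    filipin_pattern_probs: tuple[float, float, float] = (17 / 26, 8 / 26, 1 / 26)
    frac_two_alleles: float = Field(default=36 / 42, ge=0, le=1)
    frac_one_allele: float = Field(default=5 / 42, ge=0, le=1)
    allele_type_probs: dict[AlleleType, float] = Field(
        default_factory=lambda: {
            AlleleType.MISSENSE: 62 / 80,
            AlleleType.SPLICING: 2 / 80,
            AlleleType.NONSENSE: 5 / 80,
            AlleleType.DELETION: 9 / 80,
            AlleleType.INSERTION: 2 / 80,
        }
    )
    frac_splenomegaly: float = Field(default=38 / 42, ge=0, le=1)
    frac_neonatal_jaundice: float = Field(default=18 / 42, ge=0, le=1)
    frac_neonatal_organomegaly: float = Field(default=9 / 42, ge=0, le=1)

    frac_oxysterol_tested: float = Field(default=16 / 42, ge=0, le=1)
    oxysterol_triol_intercept: float = 29.0
    oxysterol_triol_slope: float = 2.0
    oxysterol_triol_noise_sd: float = 10.0
    oxysterol_7kc_intercept: float = 78.0
    oxysterol_7kc_slope: float = 5.0
    oxysterol_7kc_noise_sd: float = 20.0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if abs(sum(self.progression_mix) - 1.0) > 1e-6:
            raise ValueError("progression_mix must sum to 1")
        if any(p < 0 for p in self.progression_mix):
            raise ValueError("progression_mix proportions must be non-negative")
        if self.followup_max < self.followup_min:
            raise ValueError("followup_max must be >= followup_min")
        if abs(sum(self.filipin_pattern_probs) - 1.0) > 1e-6:
            raise ValueError("filipin_pattern_probs must sum to 1")
        if self.frac_two_alleles + self.frac_one_allele > 1 + 1e-9:
            raise ValueError("allele count fractions exceed 1")
        return self


# ---------------------------------------------------------------------------
# distribution helpers


@lru_cache(maxsize=64)
def truncnorm_parent_params(mean: float, sd: float, lower: float = 0.0) -> tuple[float, float]:
    """Parent (mu, sigma) of a lower-truncated normal whose *truncated*
    distribution has the requested mean and SD (observed cohort moments)."""
    if sd == 0:
        return mean, 0.0
    if sd / max(mean - lower, 1e-9) >= 1.0:
        raise ValueError(
            "a lower-truncated normal cannot reach CV >= 1; use a log-normal"
        )

    def eqs(x):
        m, log_s = x
        s = np.exp(log_s)
        a = (lower - m) / s
        lam = _phi(a) / max(1.0 - ndtr(a), 1e-300)
        mean_t = m + s * lam
        var_t = s**2 * (1.0 + a * lam - lam**2)
        return [mean_t - mean, np.sqrt(max(var_t, 1e-300)) - sd]

    sol = root(eqs, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"truncated-normal moment matching failed: {sol.message}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _phi(z):
    return np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi)


def _draw_truncnorm(rng, mu, sigma, lower=0.0, upper=np.inf):
    """Inverse-CDF draw from a truncated normal."""
    if sigma == 0:
        return mu
    a = ndtr((lower - mu) / sigma)
    b = ndtr((upper - mu) / sigma) if np.isfinite(upper) else 1.0
    u = rng.random()
    return mu + sigma * ndtri(a + u * (b - a))


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


# ---------------------------------------------------------------------------
# archetype time-warp and KM-median calibration


def _warp_offset(u: float, archetype: str, breakpoint: float, ratio: float, speedup: float) -> float:
    """Latent progression-time offset -> calendar offset after onset
    (steady/fulminant archetypes; the accelerated warp is mass-based)."""
    if archetype == "fulminant":
        return u / speedup
    if archetype == "accelerated":
        return u if u <= breakpoint else breakpoint + (u - breakpoint) / ratio
    return u


class _ExpectedCurve:
    """Expected latent cumulative severity C(u) = sum prev*w*F0(u).

    The accelerated archetype is defined in expected-score space: after the
    breakpoint b, symptom arrivals are scheduled so the expected score grows
    linearly at ``ratio`` times the local rate C'(b), i.e. a latent onset
    u > b maps to calendar offset b + (C(u) - C(b)) / (ratio * C'(b)).
    This makes the post/pre slope ratio of the resulting trajectory track
    the drawn ratio irrespective of where b falls on the disease course.
    """

    def __init__(self, mus, sigmas, pws):
        self.grid = np.linspace(1e-3, 80.0, 1601)
        z = (np.log(self.grid)[None, :] - np.asarray(mus)[:, None]) / np.asarray(sigmas)[:, None]
        self.C = np.asarray(pws) @ ndtr(z)

    def value(self, u: float) -> float:
        return float(np.interp(u, self.grid, self.C))

    def rate(self, u: float, h: float = 0.5) -> float:
        return max((self.value(u + h) - self.value(u - h)) / (2 * h), 1e-6)

    def accel_offset(self, u: float, b: float, ratio: float) -> float:
        if u <= b:
            return u
        return b + (self.value(u) - self.value(b)) / (ratio * self.rate(b))


def _latent_from_calendar(t: np.ndarray, b: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Inverse accelerated warp: latent offset reached by calendar time t."""
    return np.where(t <= b, t, b + (t - b) * r)


@lru_cache(maxsize=512)
def _accel_nodes(
    delay_mean: float, delay_sd: float, delay_lo: float, delay_hi: float,
    ratio_mean: float, ratio_sd: float, ratio_lo: float, ratio_hi: float,
    k: int = 24,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Deterministic quadrature nodes over (breakpoint, ratio) draws."""
    q = (np.arange(k) + 0.5) / k
    if delay_sd == 0:
        b = np.full(k, delay_mean)
    else:
        a = ndtr((delay_lo - delay_mean) / delay_sd)
        c = ndtr((delay_hi - delay_mean) / delay_sd)
        b = delay_mean + delay_sd * ndtri(a + q * (c - a))
    q2 = (((np.arange(k) * 11 + 5) % k) + 0.5) / k  # decorrelated pairing
    if ratio_sd == 0:
        r = np.full(k, min(max(ratio_mean, ratio_lo), ratio_hi))
    else:
        a = ndtr((ratio_lo - ratio_mean) / ratio_sd)
        c2 = ndtr((ratio_hi - ratio_mean) / ratio_sd)
        r = ratio_mean + ratio_sd * ndtri(a + q2 * (c2 - a))
    return tuple(b), tuple(r)


def _marginal_onset_cdf(t: float, mu: float, sigma: float, mix, f: float, nodes) -> float:
    """CDF of the calendar onset offset under the archetype mixture."""
    pi_s, pi_f, pi_a = mix
    b, r = (np.asarray(v) for v in nodes)

    def F0(x):
        x = np.asarray(x, float)
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = ndtr((np.log(x[pos]) - mu) / sigma)
        return out

    val = pi_s * F0(np.array([t]))[0] + pi_f * F0(np.array([t * f]))[0]
    if pi_a > 0:
        val += pi_a * float(np.mean(F0(_latent_from_calendar(np.full_like(b, t), b, r))))
    return val


@lru_cache(maxsize=4096)
def _calibrated_mu(
    median: float, sigma: float, prevalence: float,
    mix: tuple[float, float, float], speedup: float, accel_key: tuple,
) -> float:
    """Log-normal location such that prevalence * F_marginal(median) = 1/2
    (i.e. the cohort KM median recovers ``median``); falls back to the
    conditional median when the KM median would be undefined."""
    # a KM median only exists when prevalence clears 0.5, and it only pins
    # the latent location usefully when it does so with some margin
    if prevalence <= 0.55:
        return float(np.log(median))
    nodes = _accel_nodes(*accel_key)

    def g(mu):
        return prevalence * _marginal_onset_cdf(median, mu, sigma, mix, speedup, nodes) - 0.5

    lo, hi = np.log(median) - 12.0, np.log(median) + 12.0
    return float(brentq(g, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# generation


def _round_age(x: float) -> float:
    return float(np.round(x, 1))


def generate_cohort(
    config: GeneratorConfig,
    catalog: Optional[SymptomCatalog] = None,
    rubric: Optional[RiskIndexRubric] = None,
) -> Cohort:
    """Generate a validated cohort; simulation truths (latent archetype,
    breakpoint, slope ratio) are recorded in ``provenance`` for
    parameter-recovery tests."""
    catalog = catalog or default_catalog()
    rubric = rubric or default_rubric()
    params = config.symptom_params or {
        sid: SymptomParams(prevalence=p, median_offset=m, median_is_km=km)
        for sid, (p, m, km) in default_symptom_params().items()
    }
    unknown = sorted(set(params) - set(catalog.ids()))
    if unknown:
        raise ValueError(f"symptom_params reference unknown symptoms: {unknown}")
    seizure_ids = [e.symptom_id for e in catalog.entries if e.seizure_domain]
    seizure_sid = seizure_ids[0] if seizure_ids else None
    sorted_sids = sorted(sid for sid in params if sid not in set(seizure_ids))

    mix = tuple(config.progression_mix)
    accel_key = (
        config.accel_delay_mean, config.accel_delay_sd,
        config.accel_delay_bounds[0], config.accel_delay_bounds[1],
        config.accel_ratio_mean, config.accel_ratio_sd,
        config.accel_ratio_bounds[0], config.accel_ratio_bounds[1],
    )
    mus = np.array(
        [
            _calibrated_mu(
                params[sid].median_offset, params[sid].sigma, params[sid].prevalence,
                mix, config.fulminant_speedup, accel_key,
            )
            if params[sid].median_is_km
            else float(np.log(params[sid].median_offset))
            for sid in sorted_sids
        ]
    )
    sigmas = np.array([params[sid].sigma for sid in sorted_sids])
    prevalences = np.array([params[sid].prevalence for sid in sorted_sids])
    weights = np.array([catalog[sid].severity_weight for sid in sorted_sids])

    onset_mu, onset_sigma = truncnorm_parent_params(
        config.neuro_onset_mean, config.neuro_onset_sd, 0.0
    )
    if config.diag_delay_sd > 0:
        delay_mu, delay_sigma = lognormal_params_from_moments(
            config.diag_delay_mean, config.diag_delay_sd
        )
    else:
        delay_mu = delay_sigma = None

    # seizure probability among neurological patients such that the
    # cohort-level prevalence matches the configured value
    frac_neuro = 1.0 - config.frac_pre_neuro_diagnosis
    q_seizure = min(config.seizure_prevalence / max(frac_neuro, 1e-9), 1.0)
    pi_a = mix[2]
    if config.seizure_linked_to_acceleration:
        linked_mass = pi_a * config.accel_seizure_prob
        p_bg = max(0.0, (q_seizure - linked_mass) / max(1.0 - linked_mass, 1e-9))
    else:
        p_bg = q_seizure
    sz_mu = float(np.log(config.seizure_bg_median))
    sz_sigma = config.seizure_bg_sigma

    # expected latent severity curve (incl. an approximate seizure term)
    # driving the accelerated archetype's mass-based time warp
    curve = _ExpectedCurve(
        np.append(mus, sz_mu),
        np.append(sigmas, sz_sigma),
        np.append(
            prevalences * weights,
            q_seizure * (catalog[seizure_sid].severity_weight if seizure_sid else 0.0),
        ),
    )

    allele_types = list(config.allele_type_probs)
    allele_probs = np.array([config.allele_type_probs[t] for t in allele_types], float)
    allele_probs = allele_probs / allele_probs.sum()

    rng = np.random.default_rng(config.seed)
    patients: list[PatientRecord] = []
    truths: dict[str, dict] = {}
    width = max(4, len(str(config.n_patients)))

    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
        pre_neuro = rng.random() < config.frac_pre_neuro_diagnosis

        events: list[SymptomEvent] = []
        first_seizure: Optional[float] = None
        truth = {
            "archetype": "pre_neurological",
            "breakpoint": None,
            "slope_ratio": None,
            "seizure_from_breakpoint": False,
        }

        if pre_neuro:
            onset = None
            diagnosis = _round_age(rng.uniform(0.1, 4.0))
            last = _round_age(diagnosis + rng.uniform(config.followup_min, config.followup_max))
        else:
            onset_raw = _draw_truncnorm(rng, onset_mu, onset_sigma, lower=0.0)
            delay = (
                float(np.exp(delay_mu + delay_sigma * rng.standard_normal()))
                if delay_mu is not None
                else config.diag_delay_mean
            )
            diagnosis_raw = onset_raw + delay
            last_raw = diagnosis_raw + rng.uniform(config.followup_min, config.followup_max)

            archetype = ARCHETYPES[int(rng.choice(3, p=mix))]
            b = r = None
            if archetype == "accelerated":
                b = _draw_truncnorm(
                    rng, config.accel_delay_mean, config.accel_delay_sd,
                    lower=config.accel_delay_bounds[0], upper=config.accel_delay_bounds[1],
                )
                r = _draw_truncnorm(
                    rng, config.accel_ratio_mean, config.accel_ratio_sd,
                    lower=config.accel_ratio_bounds[0], upper=config.accel_ratio_bounds[1],
                )
                post_fu = rng.uniform(*config.post_breakpoint_followup)
                last_raw = onset_raw + b + post_fu
                diagnosis_raw = min(diagnosis_raw, last_raw - 0.5)

            onset = _round_age(onset_raw)
            diagnosis = _round_age(diagnosis_raw)
            last = _round_age(last_raw)
            truth.update(
                archetype=archetype,
                breakpoint=None if b is None else round(b, 3),
                slope_ratio=None if r is None else round(r, 3),
            )

            # symptom manifestations, sorted-id order
            u_mask = rng.random(len(sorted_sids)) < prevalences
            z = rng.standard_normal(len(sorted_sids))
            latent = np.exp(mus + sigmas * z)
            for sid, manifest, u in zip(sorted_sids, u_mask, latent):
                if not manifest:
                    continue
                if archetype == "accelerated":
                    t_off = curve.accel_offset(float(u), b, r)
                else:
                    t_off = _warp_offset(float(u), archetype, 0.0, 1.0, config.fulminant_speedup)
                age = _round_age(onset_raw + t_off)
                if age <= last:
                    events.append(SymptomEvent(symptom_id=sid, onset_age=age))

            # first seizure
            if seizure_sid is not None:
                ts = None
                linked = (
                    config.seizure_linked_to_acceleration
                    and archetype == "accelerated"
                    and rng.random() < config.accel_seizure_prob
                )
                if linked:
                    ts = b - rng.uniform(0.0, 1.0)
                    truth["seizure_from_breakpoint"] = True
                elif rng.random() < p_bg:
                    followup = last_raw - onset_raw
                    f_lo = ndtr((np.log(0.1) - sz_mu) / sz_sigma)
                    f_hi = ndtr((np.log(max(followup, 0.11)) - sz_mu) / sz_sigma)
                    if f_hi > f_lo:
                        uq = rng.uniform(f_lo, f_hi)
                        ts = float(np.exp(sz_mu + sz_sigma * ndtri(uq)))
                if ts is not None and onset_raw + ts <= last_raw:
                    age = min(_round_age(onset_raw + ts), last)
                    events.append(SymptomEvent(symptom_id=seizure_sid, onset_age=age))
                    first_seizure = age

        # diagnostic work-up
        filipin = FilipinPattern.NOT_DONE
        if rng.random() < config.frac_filipin_tested:
            filipin = (
                FilipinPattern.CLASSIC,
                FilipinPattern.VARIANT,
                FilipinPattern.INDIFFERENT,
            )[int(rng.choice(3, p=np.asarray(config.filipin_pattern_probs)))]
        u_all = rng.random()
        n_alleles = 2 if u_all < config.frac_two_alleles else (
            1 if u_all < config.frac_two_alleles + config.frac_one_allele else 0
        )
        patient_allele_types = [
            allele_types[int(k)] for k in rng.choice(len(allele_types), size=n_alleles, p=allele_probs)
        ]

        splenomegaly = bool(rng.random() < config.frac_splenomegaly)
        jaundice = bool(rng.random() < config.frac_neonatal_jaundice)
        organomegaly = bool(rng.random() < config.frac_neonatal_organomegaly)
        deceased = bool(rng.random() < config.frac_deceased)

        # risk-index answers as they would stand at diagnosis
        manifested_by_dx = {
            ev.symptom_id for ev in events if ev.onset_age <= diagnosis + 1e-9
        }
        history = {
            "splenomegaly": splenomegaly,
            "neonatal_jaundice": jaundice,
            "neonatal_organomegaly": organomegaly,
        }
        answers = {
            item: (item in manifested_by_dx) or history.get(item, False)
            for item in rubric.items
        }

        # oxysterol samples with score-correlated levels
        samples: list[OxysterolSample] = []
        if rng.random() < config.frac_oxysterol_tested and last > diagnosis:
            n_s = int(rng.choice([1, 2, 3], p=[0.2, 0.3, 0.5]))
            ages = sorted(_round_age(a) for a in rng.uniform(diagnosis, last, size=n_s))
            weights = {sid: catalog[sid].severity_weight for sid in {e.symptom_id for e in events}}
            for age in dict.fromkeys(ages):  # de-duplicated, order kept
                score = sum(
                    weights[ev.symptom_id] for ev in events if ev.onset_age <= age + 1e-9
                )
                triol = config.oxysterol_triol_intercept + config.oxysterol_triol_slope * score
                kc = config.oxysterol_7kc_intercept + config.oxysterol_7kc_slope * score
                triol += config.oxysterol_triol_noise_sd * rng.standard_normal()
                kc += config.oxysterol_7kc_noise_sd * rng.standard_normal()
                samples.append(
                    OxysterolSample(
                        age=age,
                        triol=round(max(triol, 0.5), 1),
                        seven_kc=round(max(kc, 1.0), 1),
                    )
                )

        patients.append(
            PatientRecord(
                patient_id=pid,
                sex=sex,
                age_at_assessment=last,
                age_at_neuro_onset=onset,
                age_at_diagnosis=diagnosis,
                age_at_last_visit=last,
                deceased=deceased,
                events=sorted(events, key=lambda e: (e.onset_age, e.symptom_id)),
                first_seizure_age=first_seizure,
                filipin_pattern=filipin,
                alleles_identified=n_alleles,
                allele_types=patient_allele_types,
                splenomegaly=splenomegaly,
                neonatal_jaundice=jaundice,
                neonatal_isolated_organomegaly=organomegaly,
                oxysterol_samples=samples,
                risk_index_answers=answers,
            )
        )
        truths[pid] = truth

    return Cohort(
        patients=patients,
        catalog=catalog,
        provenance={
            "generator": "npccdb.simulate.generate_cohort",
            "seed": config.seed,
            "config": config.model_dump(mode="json"),
            "truths": truths,
        },
    )


def truth_table(cohort: Cohort) -> pd.DataFrame:
    """Per-patient simulation truths (latent archetype, breakpoint, slope
    ratio) of a generated cohort; fails on imported/real cohorts."""
    truths = cohort.provenance.get("truths")
    if not truths:
        raise ValueError("no simulation provenance: not a generated cohort")
    rows = [{"patient_id": pid, **vals} for pid, vals in truths.items()]
    return pd.DataFrame(rows).set_index("patient_id")
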