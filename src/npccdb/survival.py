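"""Censored time-to-symptom estimation (product-limit) and symptom sequencing.

Each symptom's manifestation over the disease course is modelled as a
time-to-event outcome: the duration is years from neurological onset to
first manifestation; patients who never manifest the symptom contribute
their time to last visit as a censored observation.  The survival function
is estimated by the Kaplan-Meier product-limit

    S(t) = prod_{t_i <= t} (1 - d_i / n_i),

with Greenwood's variance, the median as the smallest event time with
S(t) <= 1/2, and a Brookmeyer-Crowley 95% CI for the median obtained by
inverting log(-log)-transformed pointwise confidence bands.  Ties between
events and censorings at the same time follow the standard convention that
events precede censorings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtri

from .model import Cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray  # strictly increasing event times
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    median: Optional[float]
    median_ci: Optional[tuple[Optional[float], Optional[float]]]
    n_total: int = 0

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(
    durations: Sequence[float],
    event_observed: Sequence[bool],
    alpha: float = 0.05,
) -> KMCurve:
    """Kaplan-Meier fit of right-censored durations.

    All-censored input yields S == 1 with an undefined median (no event
    times); it is not an error.
    """
    d = np.asarray(durations, dtype=float)
    e = np.asarray(event_observed, dtype=bool)
    if d.size == 0:
        raise ValueError("empty input")
    if d.shape != e.shape:
        raise ValueError("durations and event_observed must have equal length")
    if np.any(d < 0) or np.any(~np.isfinite(d)):
        raise ValueError("durations must be finite and non-negative")

    n = d.size
    event_times = np.unique(d[e])
    n_at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    for i, t in enumerate(event_times):
        # events precede censorings at tied times: a subject censored at t
        # is still at risk for an event at t
        n_at_risk[i] = int(np.sum(d >= t))
        n_events[i] = int(np.sum(e & (d == t)))

    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - n_events / n_at_risk
        survival = np.cumprod(factors)
        # Greenwood: Var[S(t)] = S(t)^2 * sum d_i / (n_i (n_i - d_i))
        terms = n_events / (n_at_risk * (n_at_risk - n_events).astype(float))
        terms[~np.isfinite(terms)] = np.inf  # n_i == d_i: variance blows up
        cum_terms = np.cumsum(terms)
        greenwood_var = survival**2 * cum_terms
        greenwood_se = np.sqrt(greenwood_var)
        greenwood_se[survival == 0.0] = 0.0

    median = _smallest_time_below(event_times, survival, 0.5)
    median_ci = _brookmeyer_crowley_ci(
        event_times, survival, cum_terms, alpha=alpha
    ) if event_times.size else None

    return KMCurve(
        times=event_times,
        n_at_risk=n_at_risk,
        n_events=n_events,
        survival=survival,
        greenwood_se=greenwood_se,
        median=median,
        median_ci=median_ci,
        n_total=n,
    )


def _smallest_time_below(times, survival, level) -> Optional[float]:
    idx = np.nonzero(survival <= level + 1e-12)[0]
    return float(times[idx[0]]) if idx.size else None


def _brookmeyer_crowley_ci(times, survival, cum_terms, alpha=0.05):
    """Median CI as the set of times where the log(-log) pointwise CI for
    S(t) still contains 1/2; bounds are the first times at which the lower
    (resp. upper) confidence band drops to 0.5."""
    z = -ndtri(alpha / 2.0)
    lower = np.empty_like(survival)
    upper = np.empty_like(survival)
    for i, s in enumerate(survival):
        if s <= 0.0:
            lower[i] = upper[i] = 0.0
        elif s >= 1.0:
            lower[i] = upper[i] = 1.0
        else:
            # se of log(-log S)
            se = np.sqrt(cum_terms[i]) / abs(np.log(s))
            theta = np.log(-np.log(s))
            lower[i] = np.exp(-np.exp(theta + z * se))
            upper[i] = np.exp(-np.exp(theta - z * se))
    lo = _smallest_time_below(times, lower, 0.5)
    hi = _smallest_time_below(times, upper, 0.5)
    return (lo, hi)


def symptom_onset_curve(cohort: Cohort, symptom_id: str) -> KMCurve:
    """KM curve of time from neurological onset to first manifestation of
    ``symptom_id``; non-manifesting patients are censored at last visit.
    Onsets recorded before neurological onset are clamped to 0 with a
    warning."""
    if symptom_id not in cohort.catalog:
        raise KeyError(f"unknown symptom {symptom_id!r}")
    durations, observed = [], []
    for p in cohort.neurological_patients:
        onset = p.onset_of(symptom_id)
        if onset is not None:
            delta = onset - p.age_at_neuro_onset
            if delta < 0:
                logger.warning(
                    "patient %s: %s manifested %.2f y before neurological "
                    "onset; clamped to 0",
                    p.patient_id, symptom_id, -delta,
                )
                delta = 0.0
            durations.append(delta)
            observed.append(True)
        else:
            durations.append(p.age_at_last_visit - p.age_at_neuro_onset)
            observed.append(False)
    if not durations:
        raise ValueError("no eligible patients with neurological onset")
    return km_fit(durations, observed)


@dataclass(frozen=True)
class SymptomRank:
    symptom_id: str
    median: Optional[float]
    median_ci: Optional[tuple[Optional[float], Optional[float]]]
    frequency: float


def rank_symptoms(
    cohort: Cohort,
    symptom_ids: Sequence[str],
    min_frequency: float = 0.4,
) -> list[SymptomRank]:
    """Symptoms manifesting in more than ``min_frequency`` of eligible
    patients, ordered by KM median onset (ascending; undefined medians
    last), ties broken by frequency descending then id."""
    if not symptom_ids:
        raise ValueError("empty symptom id list")
    if not 0.0 <= min_frequency <= 1.0:
        raise ValueError("min_frequency must be in [0, 1]")
    eligible = cohort.neurological_patients
    if not eligible:
        raise ValueError("no eligible patients with neurological onset")
    rows = []
    for sid in symptom_ids:
        freq = sum(p.has_symptom(sid) for p in eligible) / len(eligible)
        if freq <= min_frequency:
            continue
        curve = symptom_onset_curve(cohort, sid)
        rows.append(SymptomRank(sid, curve.median, curve.median_ci, freq))
    rows.sort(
        key=lambda r: (
            r.median if r.median is not None else np.inf,
            -r.frequency,
            r.symptom_id,
        )
    )
    return rows


@dataclass(frozen=True)
class OnsetDelta:
    """Symptom onset relative to diagnosis (negative = before diagnosis),
    over manifesting patients only."""

    symptom_id: str
    deltas: np.ndarray
    mean: float
    sd: float
    median: float


def onset_relative_to_diagnosis(cohort: Cohort, symptom_id: str) -> OnsetDelta:
    """Per-patient ``onset_age - age_at_diagnosis`` for ``symptom_id``."""
    if symptom_id not in cohort.catalog:
        raise KeyError(f"unknown symptom {symptom_id!r}")
    deltas = [
        p.onset_of(symptom_id) - p.age_at_diagnosis
        for p in cohort.patients
        if p.has_symptom(symptom_id)
    ]
    if not deltas:
        raise ValueError(f"no patient manifests {symptom_id!r}")
    arr = np.asarray(deltas, float)
    return OnsetDelta(
        symptom_id=symptom_id,
        deltas=arr,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        median=float(np.median(arr)),
    )
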