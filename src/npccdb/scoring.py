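"""The cumulative severity-weighted outcome score and risk-index evaluator.

The composite score of a patient at time ``t`` (years after neurological
onset) is the sum of severity weights over all catalog symptoms that have
manifested by that time — each symptom contributes once, at first
manifestation, and persists.  The *cleaned* variant excludes seizure-domain
symptoms so that disease progression around a first seizure can be measured
without the seizure's own score points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    PatientRecord,
    RiskCategory,
    RiskIndexResult,
    RiskIndexRubric,
    SymptomCatalog,
)

AGE_TOL = 1e-9

VARIANTS = ("raw", "cleaned")


class MissingNeuroOnsetError(ValueError):
    """Patient has no neurological onset; use the absolute-age API
    (:func:`compute_score_at_age`) instead of onset-relative scoring."""


class ExtrapolationError(ValueError):
    """Requested score time lies beyond the patient's follow-up."""


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")


def compute_score_at_age(
    patient: PatientRecord,
    catalog: SymptomCatalog,
    age: float,
    variant: str = "raw",
) -> float:
    """Score at an absolute age (years from birth).

    Events whose symptom_id is absent from ``catalog`` contribute nothing,
    which makes the score additive over any partition of the catalog into
    disjoint sub-catalogs.
    """
    _check_variant(variant)
    if age > patient.age_at_last_visit + AGE_TOL:
        raise ExtrapolationError(
            f"patient {patient.patient_id!r}: age {age} y beyond last visit "
            f"{patient.age_at_last_visit} y (no extrapolation)"
        )
    total = 0.0
    for ev in patient.events:
        if ev.onset_age > age + AGE_TOL:
            continue
        try:
            defn = catalog[ev.symptom_id]
        except KeyError:
            continue
        if variant == "cleaned" and defn.seizure_domain:
            continue
        total += defn.severity_weight
    return total


def compute_score(
    patient: PatientRecord,
    catalog: SymptomCatalog,
    t: float,
    variant: str = "raw",
) -> float:
    """Score at time ``t`` relative to neurological onset (years)."""
    if patient.age_at_neuro_onset is None:
        raise MissingNeuroOnsetError(
            f"patient {patient.patient_id!r} has no neurological onset; "
            "use compute_score_at_age for absolute-age scoring"
        )
    age = patient.age_at_neuro_onset + t
    if age < -AGE_TOL:
        raise ValueError(f"t={t} implies a negative absolute age")
    return compute_score_at_age(patient, catalog, age, variant)


@dataclass(frozen=True)
class ScoreTrajectory:
    """Cumulative score sampled on a regular grid of onset-relative times."""

    patient_id: str
    times: np.ndarray
    scores: np.ndarray
    variant: str = "raw"
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        t, s = np.asarray(self.times, float), np.asarray(self.scores, float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and scores must be 1-D arrays of equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(s) < -AGE_TOL):
            raise ValueError("scores must be non-decreasing (symptoms persist)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "scores", s)

    def __len__(self) -> int:
        return len(self.times)


def score_trajectory(
    patient: PatientRecord,
    catalog: SymptomCatalog,
    grid_step: float = 1.0,
    variant: str = "raw",
) -> ScoreTrajectory:
    """Score the patient on a regular grid spanning the follow-up window
    ``[0, age_at_last_visit - age_at_neuro_onset]`` (default annual)."""
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if patient.age_at_neuro_onset is None:
        raise MissingNeuroOnsetError(
            f"patient {patient.patient_id!r} has no neurological onset"
        )
    followup = patient.age_at_last_visit - patient.age_at_neuro_onset
    if followup < 0:
        raise ValueError(
            f"patient {patient.patient_id!r}: last visit precedes neurological onset"
        )
    times = np.arange(0.0, followup + 1e-9, grid_step)
    scores = np.array(
        [compute_score(patient, catalog, float(t), variant) for t in times]
    )
    return ScoreTrajectory(
        patient_id=patient.patient_id,
        times=times,
        scores=scores,
        variant=variant,
        grid_step=grid_step,
    )


def evaluate_risk_index(
    patient: PatientRecord, rubric: RiskIndexRubric
) -> RiskIndexResult:
    """Total rubric points over affirmed items; missing answers count as
    False.  Categories: total < threshold_followup -> unlikely;
    [threshold_followup, threshold_likely) -> follow-up advised;
    >= threshold_likely -> likely (boundaries inclusive on the left)."""
    if not rubric.items:
        raise ValueError("rubric has no items")
    answers = patient.risk_index_answers or {}
    total = sum(
        points for item, points in rubric.items.items() if answers.get(item, False)
    )
    if total >= rubric.threshold_likely:
        category = RiskCategory.LIKELY
    elif total >= rubric.threshold_followup:
        category = RiskCategory.FOLLOWUP
    else:
        category = RiskCategory.UNLIKELY
    return RiskIndexResult(total=total, category=category)
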