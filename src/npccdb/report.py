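"""Cohort-summary reporting: diagnostic-workup counts and integer
percentages with a fixed rounding convention (half away from zero)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import AlleleType, Cohort, FilipinPattern, RiskCategory, RiskIndexRubric
from .scoring import evaluate_risk_index


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounding halves away from zero.

    ``percent(62, 80) == 78`` (77.5 rounds up), ``percent(17, 26) == 65``.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    # exact integer arithmetic: floor((200 n + d) / (2 d))
    return (200 * numerator + denominator) // (2 * denominator)


@dataclass
class CohortSummary:
    """Descriptive diagnostic-findings layer of a cohort.

    Filipin percentages use the filipin-tested denominator; allele-type
    percentages use the total number of tallied mutant alleles; all other
    percentages use the full cohort size.  Fields that cannot be assessed
    (e.g. no patient filipin-tested) are ``None``, never a division by
    zero.
    """

    n_patients: int
    n_filipin_tested: int
    n_filipin_classic: int
    n_filipin_variant: int
    n_filipin_indifferent: int
    pct_filipin_classic: Optional[int]
    pct_filipin_variant: Optional[int]
    pct_filipin_indifferent: Optional[int]
    n_two_alleles: int
    pct_two_alleles: int
    allele_tally: dict[str, int]
    n_alleles_total: int
    pct_missense_alleles: Optional[int]
    n_neonatal_jaundice: int
    pct_neonatal_jaundice: int
    n_isolated_organomegaly: int
    pct_isolated_organomegaly: int
    n_splenomegaly: int
    pct_splenomegaly: int
    n_neurological: int
    pct_neurological: int
    n_seizure: int
    pct_seizure: int
    diag_delay_mean: Optional[float]
    diag_delay_sd: Optional[float]
    assessment_age_mean: float
    assessment_age_sd: float
    risk_index_counts: dict[str, int] = field(default_factory=dict)
    pct_si_likely: Optional[int] = None
    pct_si_followup: Optional[int] = None
    pct_si_unlikely: Optional[int] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def cohort_summary(cohort: Cohort, rubric: Optional[RiskIndexRubric] = None) -> CohortSummary:
    """Compute every summary field from the patient records."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n = len(cohort)
    pats = cohort.patients

    tested = [p for p in pats if p.filipin_pattern is not FilipinPattern.NOT_DONE]
    n_tested = len(tested)
    n_classic = sum(p.filipin_pattern is FilipinPattern.CLASSIC for p in tested)
    n_variant = sum(p.filipin_pattern is FilipinPattern.VARIANT for p in tested)
    n_indiff = sum(p.filipin_pattern is FilipinPattern.INDIFFERENT for p in tested)

    n_two = sum(p.alleles_identified == 2 for p in pats)

    if cohort.allele_tally is not None:
        tally = {t.value: int(c) for t, c in cohort.allele_tally.items()}
    else:
        tally = {}
        for p in pats:
            for t in p.allele_types:
                tally[t.value] = tally.get(t.value, 0) + 1
    n_alleles = sum(tally.values())
    n_missense = tally.get(AlleleType.MISSENSE.value, 0)

    n_jaundice = sum(bool(p.neonatal_jaundice) for p in pats)
    n_organo = sum(bool(p.neonatal_isolated_organomegaly) for p in pats)
    n_spleno = sum(bool(p.splenomegaly) for p in pats)
    n_neuro = sum(p.age_at_neuro_onset is not None for p in pats)
    n_seiz = sum(p.first_seizure_age is not None for p in pats)

    delays = [
        p.disease_duration_at_diagnosis
        for p in pats
        if p.disease_duration_at_diagnosis is not None
    ]
    ages = np.array([p.age_at_assessment for p in pats], float)

    si_counts: dict[str, int] = {}
    pct_likely = pct_follow = pct_unlikely = None
    if rubric is not None:
        cats = [
            evaluate_risk_index(p, rubric).category
            for p in pats
            if p.risk_index_answers is not None
        ]
        si_counts = {c.value: sum(x is c for x in cats) for c in RiskCategory}
        if cats:
            pct_likely = percent(si_counts["likely"], n)
            pct_follow = percent(si_counts["followup"], n)
            pct_unlikely = percent(si_counts["unlikely"], n)

    return CohortSummary(
        n_patients=n,
        n_filipin_tested=n_tested,
        n_filipin_classic=n_classic,
        n_filipin_variant=n_variant,
        n_filipin_indifferent=n_indiff,
        pct_filipin_classic=percent(n_classic, n_tested) if n_tested else None,
        pct_filipin_variant=percent(n_variant, n_tested) if n_tested else None,
        pct_filipin_indifferent=percent(n_indiff, n_tested) if n_tested else None,
        n_two_alleles=n_two,
        pct_two_alleles=percent(n_two, n),
        allele_tally=tally,
        n_alleles_total=n_alleles,
        pct_missense_alleles=percent(n_missense, n_alleles) if n_alleles else None,
        n_neonatal_jaundice=n_jaundice,
        pct_neonatal_jaundice=percent(n_jaundice, n),
        n_isolated_organomegaly=n_organo,
        pct_isolated_organomegaly=percent(n_organo, n),
        n_splenomegaly=n_spleno,
        pct_splenomegaly=percent(n_spleno, n),
        n_neurological=n_neuro,
        pct_neurological=percent(n_neuro, n),
        n_seizure=n_seiz,
        pct_seizure=percent(n_seiz, n),
        diag_delay_mean=float(np.mean(delays)) if delays else None,
        diag_delay_sd=float(np.std(delays, ddof=1)) if len(delays) > 1 else None,
        assessment_age_mean=float(ages.mean()),
        assessment_age_sd=float(ages.std(ddof=1)) if len(ages) > 1 else 0.0,
        risk_index_counts=si_counts,
        pct_si_likely=pct_likely,
        pct_si_followup=pct_follow,
        pct_si_unlikely=pct_unlikely,
    )
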