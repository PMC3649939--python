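"""Synthetic reference cohort encoding the published diagnostic marginals.

The original 42-patient registry cohort is not public.  This module builds
a fully synthetic stand-in whose *diagnostic-findings marginals* match the
printed cohort description: 26 filipin-tested (17 classic / 8 variant / 1
indifferent), 36 patients with both disease alleles identified, a mutant-
allele tally of 80 (62 missense, 2 splicing, 5 nonsense, 9 deletions, 2
insertions), 18 with prolonged neonatal jaundice, 9 with isolated neonatal
organomegaly, 38 with splenomegaly and a documented neurological onset (4
diagnosed pre-neurologically), 15 with seizures, and screening-index
categories 30 likely / 7 follow-up / 5 unlikely.

Only the marginals are meaningful; per-patient combinations and ages are
arbitrary.  The allele tally is carried at cohort level because the
printed total (80) exceeds what the per-patient identified-allele counts
(36x2 + 5x1 = 77) can reach — an inconsistency of the published counts
that is reproduced, not repaired.
"""

from __future__ import annotations

from .catalog_default import default_catalog, default_rubric
from .model import AlleleType, Cohort, FilipinPattern, PatientRecord

N = 42


def _take(flags_left: dict[str, int], key: str) -> bool:
    if flags_left.get(key, 0) > 0:
        flags_left[key] -= 1
        return True
    return False


def reference_marginals_cohort() -> Cohort:
    """Build the 42-patient synthetic cohort with the printed marginals."""
    rubric = default_rubric()
    left = {
        "filipin_classic": 17,
        "filipin_variant": 8,
        "filipin_indifferent": 1,
        "two_alleles": 36,
        "one_allele": 5,
        "jaundice": 18,
        "organomegaly": 9,
        "splenomegaly": 38,
        "neuro": 38,
        "seizure": 15,
        "si_likely": 30,
        "si_followup": 7,
    }
    patients = []
    for i in range(N):
        pid = f"R{i + 1:03d}"
        if _take(left, "filipin_classic"):
            filipin = FilipinPattern.CLASSIC
        elif _take(left, "filipin_variant"):
            filipin = FilipinPattern.VARIANT
        elif _take(left, "filipin_indifferent"):
            filipin = FilipinPattern.INDIFFERENT
        else:
            filipin = FilipinPattern.NOT_DONE
        alleles = 2 if _take(left, "two_alleles") else (1 if _take(left, "one_allele") else 0)

        neuro = _take(left, "neuro")
        onset = 5.0 + 0.1 * i if neuro else None
        diagnosis = (onset + 4.0) if neuro else 1.0 + 0.1 * i
        last = diagnosis + 5.0
        seizure_age = (onset + 6.0) if (neuro and _take(left, "seizure")) else None

        # screening-index categories via answers against the default rubric
        if _take(left, "si_likely"):
            answers = {"vsgp": True, "gelastic_cataplexy": True}  # 80 points
        elif _take(left, "si_followup"):
            answers = {"splenomegaly": True}  # 40 points
        else:
            answers = {"clumsiness": True}  # 5 points

        patients.append(
            PatientRecord(
                patient_id=pid,
                age_at_assessment=last,
                age_at_neuro_onset=onset,
                age_at_diagnosis=diagnosis,
                age_at_last_visit=last,
                deceased=i < 8,
                events=[],
                first_seizure_age=seizure_age,
                filipin_pattern=filipin,
                alleles_identified=alleles,
                splenomegaly=_take(left, "splenomegaly"),
                neonatal_jaundice=_take(left, "jaundice"),
                neonatal_isolated_organomegaly=_take(left, "organomegaly"),
                risk_index_answers=answers,
            )
        )
    return Cohort(
        patients=patients,
        catalog=default_catalog(),
        provenance={"source": "synthetic reference marginals (n=42)"},
        allele_tally={
            AlleleType.MISSENSE: 62,
            AlleleType.SPLICING: 2,
            AlleleType.NONSENSE: 5,
            AlleleType.DELETION: 9,
            AlleleType.INSERTION: 2,
        },
    )
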