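"""Shipped default symptom catalog and screening rubric.

The default catalog holds 72 neuropsychiatric signs plus visceral items.
The signs that are named in the published cohort descriptions (cognitive
impairment, clumsiness, impaired fine motor skills, ataxia, dysarthria,
vertical supranuclear gaze palsy, ...) carry the reported manifestation
prevalences and Kaplan-Meier median onset offsets; the remainder of the
72-sign inventory is NOT public, so those entries are placeholder
reconstructions (ids ``np_sign_NN``) with prevalences below 0.4 and onset
medians spread over the disease course.  Severity weights use a three-tier
scheme (1 mild / 2 moderate / 4 severe); both weights and onset parameters
are configuration, so a verbatim scoring rubric can be dropped in.

Hearing/auditory evaluation is excluded from the default scored inventory
(such testing is rarely available across a retrospective cohort).
"""

from __future__ import annotations

from .model import RiskIndexRubric, SymptomCatalog, SymptomCategory, SymptomDefinition

CATALOG_VERSION = "default-reconstruction-1"

# (symptom_id, label, category, weight, prevalence, median onset offset [y])
# Prevalences/medians for the named signs follow the published cohort
# statistics; the rest are plausible placeholders.
_NAMED = [
    ("cognitive_impairment", "Cognitive impairment", SymptomCategory.COGNITION, 2, 0.86, 3.4),
    ("clumsiness", "Clumsiness", SymptomCategory.NEUROLOGICAL_MOTOR, 1, 0.81, 3.7),
    ("dysarthria", "Dysarthria", SymptomCategory.SPEECH, 2, 0.81, 6.9),
    ("impaired_fine_motor_skills", "Impaired fine motor skills", SymptomCategory.NEUROLOGICAL_MOTOR, 1, 0.79, 3.4),
    ("ataxia", "Ataxia", SymptomCategory.NEUROLOGICAL_MOTOR, 2, 0.79, 7.5),
    ("vsgp", "Vertical supranuclear gaze palsy", SymptomCategory.NEUROLOGICAL_OCULAR, 2, 0.76, 7.4),
    ("learning_disability", "Learning disability", SymptomCategory.COGNITION, 1, 0.72, 4.0),
    ("balance_problems", "Balance problems", SymptomCategory.NEUROLOGICAL_MOTOR, 1, 0.70, 4.5),
    ("gait_disturbance", "Gait disturbance", SymptomCategory.NEUROLOGICAL_MOTOR, 2, 0.68, 5.5),
    ("memory_deficits", "Memory deficits", SymptomCategory.COGNITION, 1, 0.65, 5.0),
    ("impaired_saccades", "Impaired saccadic eye movements", SymptomCategory.NEUROLOGICAL_OCULAR, 1, 0.62, 6.5),
    ("attention_deficit", "Attention deficit", SymptomCategory.COGNITION, 1, 0.60, 4.2),
    ("behavioral_problems", "Behavioural problems", SymptomCategory.PSYCHIATRIC, 1, 0.58, 5.8),
    ("slowed_speech", "Slowed speech", SymptomCategory.SPEECH, 1, 0.55, 7.0),
    ("dysphagia", "Dysphagia", SymptomCategory.NEUROLOGICAL_MOTOR, 2, 0.55, 9.5),
    ("dystonia", "Dystonia", SymptomCategory.NEUROLOGICAL_MOTOR, 2, 0.55, 10.0),
    ("gelastic_cataplexy", "Gelastic cataplexy", SymptomCategory.NEUROLOGICAL_MOTOR, 2, 0.50, 8.5),
    ("tremor", "Tremor", SymptomCategory.NEUROLOGICAL_MOTOR, 1, 0.48, 9.0),
    ("muscular_hypotonia", "Muscular hypotonia", SymptomCategory.NEUROLOGICAL_MOTOR, 1, 0.45, 6.0),
    ("dysmetria", "Dysmetria", SymptomCategory.NEUROLOGICAL_MOTOR, 1, 0.43, 8.0),
    ("spasticity", "Spasticity", SymptomCategory.NEUROLOGICAL_MOTOR, 2, 0.42, 12.0),
    # seizures: onset handled by the generator's dedicated seizure machinery
    ("seizures", "Epileptic seizures", SymptomCategory.SEIZURE, 4, 0.35, 8.0),
    ("psychosis", "Schizophrenia-like psychosis", SymptomCategory.PSYCHIATRIC, 2, 0.25, 14.0),
    ("depression", "Depression", SymptomCategory.PSYCHIATRIC, 1, 0.20, 13.0),
    ("loss_of_ambulation", "Loss of independent ambulation", SymptomCategory.NEUROLOGICAL_MOTOR, 4, 0.30, 14.0),
    ("dementia", "Dementia", SymptomCategory.COGNITION, 4, 0.28, 15.0),
    ("incontinence", "Incontinence", SymptomCategory.NEUROLOGICAL_MOTOR, 2, 0.25, 13.5),
    ("social_withdrawal", "Social withdrawal", SymptomCategory.SOCIAL, 1, 0.30, 9.5),
    ("developmental_delay", "Developmental delay", SymptomCategory.DEVELOPMENT, 2, 0.35, 1.5),
    ("sleep_disturbance", "Sleep disturbance", SymptomCategory.OTHER, 1, 0.30, 6.8),
]

_N_TOTAL_NEURO = 72
_SEIZURE_DOMAIN_IDS = {"seizures"}

_VISCERAL = [
    ("splenomegaly", "Splenomegaly", 1),
    ("hepatomegaly", "Hepatomegaly", 1),
    ("neonatal_jaundice", "Prolonged neonatal jaundice", 1),
    ("neonatal_organomegaly", "Isolated neonatal organomegaly", 1),
]


# Placeholder onset medians, weights and prevalences were designed so that
# the *latent* expected cumulative severity — named signs plus placeholders —
# accumulates near-linearly over the first three disease decades (constant
# residual onset-mass density around the named signs' 3-9 y cluster),
# emulating the near-linear mean progression observed in registry cohorts.
_PLACEHOLDER_DESIGN = [
    (0.3, 2, 0.635), (0.86, 2, 0.635), (1.63, 2, 0.635), (6.84, 2, 0.635),
    (8.91, 2, 0.635), (10.14, 2, 0.635), (11.13, 2, 0.635), (12.0, 2, 0.635),
    (12.8, 2, 0.635), (13.55, 2, 0.635), (14.26, 2, 0.635), (14.94, 2, 0.635),
    (15.6, 2, 0.635), (16.23, 2, 0.635), (16.86, 2, 0.635), (17.47, 2, 0.635),
    (18.07, 2, 0.635), (18.66, 2, 0.635), (19.25, 2, 0.635), (19.82, 2, 0.635),
    (20.39, 2, 0.635), (20.96, 2, 0.635), (21.52, 2, 0.635), (22.08, 2, 0.635),
    (22.63, 2, 0.635), (23.18, 2, 0.635), (23.73, 2, 0.635), (24.27, 2, 0.635),
    (24.82, 2, 0.635), (25.36, 2, 0.635), (25.9, 2, 0.635), (26.43, 2, 0.635),
    (26.97, 2, 0.635), (27.5, 2, 0.635), (28.04, 2, 0.635), (28.57, 2, 0.635),
    (29.1, 2, 0.635), (29.63, 2, 0.635), (30.16, 2, 0.635), (30.68, 2, 0.635),
    (31.21, 2, 0.635), (31.74, 2, 0.635),
]


def _placeholder_rows() -> list[tuple]:
    """Placeholder reconstructions filling the inventory to 72 signs."""
    n = _N_TOTAL_NEURO - len(_NAMED)
    assert n == len(_PLACEHOLDER_DESIGN)
    cats = [
        SymptomCategory.NEUROLOGICAL_MOTOR,
        SymptomCategory.COGNITION,
        SymptomCategory.PSYCHIATRIC,
        SymptomCategory.NEUROLOGICAL_OCULAR,
        SymptomCategory.SPEECH,
        SymptomCategory.DEVELOPMENT,
        SymptomCategory.SOCIAL,
    ]
    rows = []
    for k, (median, weight, prevalence) in enumerate(_PLACEHOLDER_DESIGN):
        rows.append(
            (
                f"np_sign_{k + 1:02d}",
                f"Neuropsychiatric sign (placeholder {k + 1})",
                cats[k % len(cats)],
                weight,
                prevalence,
                median,
            )
        )
    return rows


def default_symptom_rows() -> list[tuple]:
    """All scored neuropsychiatric rows: (id, label, category, weight,
    prevalence, median onset offset)."""
    return list(_NAMED) + _placeholder_rows()


def default_catalog() -> SymptomCatalog:
    entries = [
        SymptomDefinition(
            symptom_id=sid,
            label=label,
            category=cat,
            severity_weight=float(w),
            seizure_domain=sid in _SEIZURE_DOMAIN_IDS,
        )
        for sid, label, cat, w, _prev, _med in default_symptom_rows()
    ]
    entries += [
        SymptomDefinition(
            symptom_id=sid,
            label=label,
            category=SymptomCategory.VISCERAL,
            severity_weight=float(w),
        )
        for sid, label, w in _VISCERAL
    ]
    return SymptomCatalog(entries=entries, version=CATALOG_VERSION)


def default_symptom_params() -> dict[str, tuple[float, float, bool]]:
    """Per-symptom generator parameters: (prevalence, median onset offset in
    years after neurological onset, median_is_km).  The named signs'
    medians are published cohort-level Kaplan-Meier medians
    (``median_is_km=True``); the placeholder reconstructions' medians are
    conditional onset medians.  Seizure-domain signs are excluded (their
    timing has its own mechanism)."""
    return {
        sid: (prev, med, not sid.startswith("np_sign_"))
        for sid, _l, _c, _w, prev, med in default_symptom_rows()
        if sid not in _SEIZURE_DOMAIN_IDS
    }


def default_rubric() -> RiskIndexRubric:
    """Small synthetic screening rubric (NOT the published Suspicion-Index
    weights, which are treated as user-supplied configuration).  Items are
    keyed by symptom/history ids so answers can be derived from a record."""
    return RiskIndexRubric(
        items={
            "vsgp": 40.0,
            "gelastic_cataplexy": 40.0,
            "splenomegaly": 40.0,
            "cognitive_impairment": 20.0,
            "ataxia": 20.0,
            "dysarthria": 15.0,
            "psychosis": 10.0,
            "seizures": 10.0,
            "neonatal_jaundice": 10.0,
            "clumsiness": 5.0,
        },
        threshold_followup=40.0,
        threshold_likely=70.0,
    )
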