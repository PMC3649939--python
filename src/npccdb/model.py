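"""Domain types for registry-style NP-C cohort data.

Ages are decimal years relative to birth; all within-disease times are
expressed relative to the age at first neurological sign ("neurological
onset"), the t = 0 of every trajectory-level analysis.  Symptoms are
recorded by first manifestation only and are assumed to persist, so a
patient's event list holds at most one entry per symptom.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, Field, model_validator

#: numerical slack for age comparisons (ages are ~0.1-y resolution data)
AGE_TOL = 1e-6


class CohortValidationError(ValueError):
    """A cohort, patient or catalog violated a structural invariant."""


class UnknownSymptomError(CohortValidationError):
    """An event references a symptom_id absent from the catalog."""


class SymptomCategory(str, enum.Enum):
    NEUROLOGICAL_MOTOR = "neurological-motor"
    NEUROLOGICAL_OCULAR = "neurological-ocular"
    COGNITION = "cognition"
    PSYCHIATRIC = "psychiatric"
    SPEECH = "speech"
    SEIZURE = "seizure"
    DEVELOPMENT = "development"
    SOCIAL = "social"
    VISCERAL = "visceral"
    OTHER = "other"


class FilipinPattern(str, enum.Enum):
    CLASSIC = "classic"
    VARIANT = "variant"
    INDIFFERENT = "indifferent"
    NOT_DONE = "not_done"


class AlleleType(str, enum.Enum):
    MISSENSE = "missense"
    SPLICING = "splicing"
    NONSENSE = "nonsense"
    DELETION = "deletion"
    INSERTION = "insertion"


class Sex(str, enum.Enum):
    FEMALE = "f"
    MALE = "m"


class SymptomDefinition(BaseModel):
    """One scored clinical sign.

    ``severity_weight`` is the number of score points the sign contributes
    to the cumulative outcome score once it has manifested.
    ``seizure_domain`` marks signs removed by the seizure-"cleaned" score
    variant used to test whether seizures predict accelerated progression.
    """

    symptom_id: str = Field(min_length=1)
    label: str
    category: SymptomCategory
    severity_weight: float = Field(gt=0)
    seizure_domain: bool = False

    @model_validator(mode="after")
    def _seizure_domain_implies_category(self) -> "SymptomDefinition":
        if self.seizure_domain and self.category is not SymptomCategory.SEIZURE:
            raise ValueError(
                f"symptom {self.symptom_id!r}: seizure_domain=True requires "
                f"category 'seizure', got {self.category.value!r}"
            )
        return self


class SymptomCatalog(BaseModel):
    entries: list[SymptomDefinition] = Field(min_length=1)
    version: str = "unversioned"

    @model_validator(mode="after")
    def _unique_ids(self) -> "SymptomCatalog":
        seen: set[str] = set()
        for e in self.entries:
            if e.symptom_id in seen:
                raise ValueError(f"duplicate symptom_id {e.symptom_id!r} in catalog")
            seen.add(e.symptom_id)
        return self

    def ids(self) -> list[str]:
        return [e.symptom_id for e in self.entries]

    def __contains__(self, symptom_id: str) -> bool:
        return any(e.symptom_id == symptom_id for e in self.entries)

    def __getitem__(self, symptom_id: str) -> SymptomDefinition:
        for e in self.entries:
            if e.symptom_id == symptom_id:
                return e
        raise KeyError(symptom_id)

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, symptom_ids: list[str], version: Optional[str] = None) -> "SymptomCatalog":
        """Sub-catalog restricted to ``symptom_ids`` (order preserved)."""
        wanted = set(symptom_ids)
        return SymptomCatalog(
            entries=[e for e in self.entries if e.symptom_id in wanted],
            version=version or f"{self.version}/subset",
        )

    def min_weight(self) -> float:
        return min(e.severity_weight for e in self.entries)


class SymptomEvent(BaseModel):
    """First manifestation of one symptom in one patient."""

    symptom_id: str = Field(min_length=1)
    onset_age: float = Field(ge=0)


class OxysterolSample(BaseModel):
    """One plasma oxysterol measurement (ng/mL) at a given age."""

    age: float = Field(ge=0)
    triol: Optional[float] = Field(default=None, ge=0)
    seven_kc: Optional[float] = Field(default=None, ge=0)


class PatientRecord(BaseModel):
    patient_id: str = Field(min_length=1)
    sex: Optional[Sex] = None
    age_at_assessment: float = Field(ge=0)
    #: age at first neurological sign; None for purely visceral /
    #: pre-symptomatic patients (excluded from onset-normalised analyses)
    age_at_neuro_onset: Optional[float] = Field(default=None, ge=0)
    age_at_diagnosis: float = Field(ge=0)
    age_at_last_visit: float = Field(ge=0)
    deceased: bool = False
    events: list[SymptomEvent] = Field(default_factory=list)
    first_seizure_age: Optional[float] = Field(default=None, ge=0)
    filipin_pattern: FilipinPattern = FilipinPattern.NOT_DONE
    alleles_identified: int = Field(default=0, ge=0, le=2)
    allele_types: list[AlleleType] = Field(default_factory=list, max_length=2)
    splenomegaly: Optional[bool] = None
    neonatal_jaundice: Optional[bool] = None
    neonatal_isolated_organomegaly: Optional[bool] = None
    oxysterol_samples: list[OxysterolSample] = Field(default_factory=list)
    risk_index_answers: Optional[dict[str, bool]] = None
    sibling_group: Optional[str] = None

    @model_validator(mode="after")
    def _check_invariants(self) -> "PatientRecord":
        seen: set[str] = set()
        for ev in self.events:
            if ev.symptom_id in seen:
                raise ValueError(
                    f"patient {self.patient_id!r}: symptom {ev.symptom_id!r} "
                    "recorded more than once (events are first manifestations)"
                )
            seen.add(ev.symptom_id)
            if ev.onset_age > self.age_at_last_visit + AGE_TOL:
                raise ValueError(
                    f"patient {self.patient_id!r}: onset of {ev.symptom_id!r} at "
                    f"{ev.onset_age} y exceeds age_at_last_visit "
                    f"{self.age_at_last_visit} y"
                )
        if (
            self.first_seizure_age is not None
            and self.first_seizure_age > self.age_at_last_visit + AGE_TOL
        ):
            raise ValueError(
                f"patient {self.patient_id!r}: first_seizure_age beyond last visit"
            )
        return self

    def has_symptom(self, symptom_id: str) -> bool:
        return any(ev.symptom_id == symptom_id for ev in self.events)

    def onset_of(self, symptom_id: str) -> Optional[float]:
        for ev in self.events:
            if ev.symptom_id == symptom_id:
                return ev.onset_age
        return None

    @property
    def followup_from_onset(self) -> Optional[float]:
        if self.age_at_neuro_onset is None:
            return None
        return self.age_at_last_visit - self.age_at_neuro_onset

    @property
    def disease_duration_at_diagnosis(self) -> Optional[float]:
        """Years from first neurological sign to diagnosis (negative when
        diagnosis preceded neurological onset)."""
        if self.age_at_neuro_onset is None:
            return None
        return self.age_at_diagnosis - self.age_at_neuro_onset


class Cohort(BaseModel):
    patients: list[PatientRecord]
    catalog: SymptomCatalog
    #: free-form metadata: file source, or generator config/seed and
    #: per-patient simulation truths
    provenance: dict = Field(default_factory=dict)
    #: optional cohort-level tally of mutant alleles by variant type; used
    #: when per-patient allele typing is incomplete (registry summaries often
    #: report family-level allele tables whose total exceeds the per-patient
    #: identified-allele count)
    allele_tally: Optional[dict[AlleleType, int]] = None

    @model_validator(mode="after")
    def _check_invariants(self) -> "Cohort":
        seen: set[str] = set()
        for p in self.patients:
            if p.patient_id in seen:
                raise ValueError(f"duplicate patient_id {p.patient_id!r}")
            seen.add(p.patient_id)
        unresolved = sorted(
            {
                ev.symptom_id
                for p in self.patients
                for ev in p.events
                if ev.symptom_id not in self.catalog
            }
        )
        if unresolved:
            raise UnknownSymptomError(
                f"events reference symptom_ids absent from catalog: {unresolved}"
            )
        seizure_ids = {
            e.symptom_id for e in self.catalog.entries if e.seizure_domain
        }
        for p in self.patients:
            onsets = [
                ev.onset_age for ev in p.events if ev.symptom_id in seizure_ids
            ]
            if onsets:
                first = min(onsets)
                if p.first_seizure_age is None or abs(p.first_seizure_age - first) > 1e-6:
                    raise ValueError(
                        f"patient {p.patient_id!r}: first_seizure_age must equal "
                        f"the earliest seizure-domain event onset ({first} y)"
                    )
        return self

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def neurological_patients(self) -> list[PatientRecord]:
        """Patients with a documented neurological onset (the onset-normalised
        analysis population)."""
        return [p for p in self.patients if p.age_at_neuro_onset is not None]

    def __getitem__(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


class RiskIndexRubric(BaseModel):
    """Point-weighted screening rubric (Suspicion-Index style).

    ``items`` maps item ids (conventionally symptom ids, or visceral-history
    ids like ``splenomegaly``) to score points; the category thresholds
    default to the published 40 (follow-up advised) and 70 (testing likely
    warranted) cut points.
    """

    items: dict[str, float] = Field(min_length=1)
    threshold_followup: float = 40.0
    threshold_likely: float = 70.0

    @model_validator(mode="after")
    def _ordered_thresholds(self) -> "RiskIndexRubric":
        if not self.threshold_followup < self.threshold_likely:
            raise ValueError(
                "threshold_followup must be strictly below threshold_likely"
            )
        return self


class RiskCategory(str, enum.Enum):
    UNLIKELY = "unlikely"
    FOLLOWUP = "followup"
    LIKELY = "likely"


class RiskIndexResult(BaseModel):
    total: float
    category: RiskCategory
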