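"""Readers/writers for cohort data and configuration.

Two interchange formats are supported:

* **JSON** — a single nested document holding catalog, patients, optional
  allele tally and provenance.  This is the lossless, canonical form.
* **CSV** — a directory with ``patients.csv`` (one row per patient) and a
  long-format ``events.csv`` keyed by (patient_id, symptom_id), plus
  ``catalog.yaml`` and ``provenance.json``.  Nested per-patient fields
  (oxysterol samples, risk-index answers, allele types) are serialised as
  JSON strings inside their ``patients.csv`` cells.

Symptom catalogs and risk-index rubrics load from YAML or JSON config
files.  All readers validate structural invariants and raise typed errors
(:class:`~npccdb.model.CohortValidationError` subclasses or pydantic
``ValidationError``) rather than silently coercing malformed input.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .model import (
    Cohort,
    CohortValidationError,
    PatientRecord,
    RiskIndexRubric,
    SymptomCatalog,
)

PathLike = Union[str, Path]

_PATIENT_JSON_CELLS = ("allele_types", "oxysterol_samples", "risk_index_answers")


def _cohort_to_doc(cohort: Cohort) -> dict:
    return cohort.model_dump(mode="json")


def _doc_to_cohort(doc: dict) -> Cohort:
    try:
        return Cohort.model_validate(doc)
    except ValidationError as exc:
        # re-raise with a compact, field-naming message
        raise CohortValidationError(_summarise_validation_error(exc)) from exc


def _summarise_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors()[:10]:
        loc = ".".join(str(x) for x in err["loc"])
        lines.append(f"{loc}: {err['msg']}")
    return "cohort failed validation: " + "; ".join(lines)


def write_cohort(cohort: Cohort, path: PathLike, format: str = "json") -> Path:
    """Serialise a cohort; returns the path written.

    ``format='json'`` writes a single file; ``format='csv'`` writes the
    patients/events CSV pair (plus catalog and provenance side files) into
    the directory ``path``.  Serialisation is deterministic (sorted keys),
    so identical cohorts yield byte-identical files.
    """
    path = Path(path)
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(_cohort_to_doc(cohort), indent=1, sort_keys=True) + "\n"
        )
        return path
    if format != "csv":
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")

    path.mkdir(parents=True, exist_ok=True)
    rows = []
    event_rows = []
    for p in cohort.patients:
        d = p.model_dump(mode="json")
        events = d.pop("events")
        for ev in events:
            event_rows.append({"patient_id": p.patient_id, **ev})
        for key in _PATIENT_JSON_CELLS:
            d[key] = json.dumps(d[key], sort_keys=True)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path / "patients.csv", index=False)
    pd.DataFrame(
        event_rows, columns=["patient_id", "symptom_id", "onset_age"]
    ).to_csv(path / "events.csv", index=False)
    (path / "catalog.yaml").write_text(
        yaml.safe_dump(cohort.catalog.model_dump(mode="json"), sort_keys=True)
    )
    side = {"provenance": cohort.provenance}
    if cohort.allele_tally is not None:
        side["allele_tally"] = {k.value: v for k, v in cohort.allele_tally.items()}
    (path / "provenance.json").write_text(json.dumps(side, indent=1, sort_keys=True) + "\n")
    return path


def read_cohort(path: PathLike, format: str = "json") -> Cohort:
    """Read and validate a cohort written by :func:`write_cohort`."""
    path = Path(path)
    if format == "json":
        if not path.is_file():
            raise FileNotFoundError(path)
        return _doc_to_cohort(json.loads(path.read_text()))
    if format != "csv":
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")

    patients_df = pd.read_csv(path / "patients.csv")
    events_path = path / "events.csv"
    events_df = (
        pd.read_csv(events_path)
        if events_path.exists()
        else pd.DataFrame(columns=["patient_id", "symptom_id", "onset_age"])
    )
    if patients_df["patient_id"].duplicated().any():
        dups = sorted(patients_df["patient_id"][patients_df["patient_id"].duplicated()])
        raise CohortValidationError(f"duplicate patient_id rows in patients.csv: {dups}")

    events_by_patient: dict[str, list[dict]] = {}
    for rec in events_df.to_dict("records"):
        events_by_patient.setdefault(str(rec["patient_id"]), []).append(
            {"symptom_id": rec["symptom_id"], "onset_age": rec["onset_age"]}
        )
    unknown_patients = set(events_by_patient) - set(patients_df["patient_id"].astype(str))
    if unknown_patients:
        raise CohortValidationError(
            f"events.csv references unknown patient_ids: {sorted(unknown_patients)}"
        )

    patients = []
    for rec in patients_df.to_dict("records"):
        rec = {k: (None if _is_na_scalar(v) else v) for k, v in rec.items()}
        for key in _PATIENT_JSON_CELLS:
            if isinstance(rec.get(key), str):
                rec[key] = json.loads(rec[key])
            elif rec.get(key) is None:
                rec[key] = None if key == "risk_index_answers" else []
        rec["events"] = events_by_patient.get(str(rec["patient_id"]), [])
        try:
            patients.append(PatientRecord.model_validate(rec))
        except ValidationError as exc:
            raise CohortValidationError(
                f"patient {rec.get('patient_id')!r}: {_summarise_validation_error(exc)}"
            ) from exc

    catalog = load_symptom_catalog(path / "catalog.yaml")
    side_path = path / "provenance.json"
    side = json.loads(side_path.read_text()) if side_path.exists() else {}
    return _doc_to_cohort(
        {
            "patients": [p.model_dump(mode="json") for p in patients],
            "catalog": catalog.model_dump(mode="json"),
            "provenance": side.get("provenance", {}),
            "allele_tally": side.get("allele_tally"),
        }
    )


def _is_na_scalar(v) -> bool:
    try:
        return v is None or (pd.isna(v) if not isinstance(v, (list, dict)) else False)
    except (TypeError, ValueError):
        return False


def _load_config(path: PathLike) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def load_symptom_catalog(path: PathLike) -> SymptomCatalog:
    """Load a symptom catalog from a YAML/JSON config file."""
    doc = _load_config(path)
    try:
        return SymptomCatalog.model_validate(doc)
    except ValidationError as exc:
        raise CohortValidationError(
            f"catalog {path}: {_summarise_validation_error(exc)}"
        ) from exc


def load_risk_rubric(path: PathLike) -> RiskIndexRubric:
    """Load a risk-index rubric from a YAML/JSON config file."""
    doc = _load_config(path)
    try:
        return RiskIndexRubric.model_validate(doc)
    except ValidationError as exc:
        raise CohortValidationError(
            f"rubric {path}: {_summarise_validation_error(exc)}"
        ) from exc
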