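import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import npccdb as ncdb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# fixed study-condition seed for the shared simulated cohorts
COHORT_SEED = 1234


@pytest.fixture(scope="session")
def cohort500():
    """Default generated cohort (n=500) shared across recovery tests."""
    return ncdb.generate_cohort(ncdb.GeneratorConfig(n_patients=500, seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort500_analysis(cohort500):
    """Annual trajectories, cohort envelope, truth table and progression
    calls for the shared n=500 cohort."""
    trajs = {
        p.patient_id: ncdb.score_trajectory(p, cohort500.catalog)
        for p in cohort500.neurological_patients
    }
    fit, env = ncdb.cohort_trend(list(trajs.values()))
    truth = ncdb.truth_table(cohort500)
    calls = {pid: ncdb.classify_progression(t, env) for pid, t in trajs.items()}
    return {"trajectories": trajs, "trend": fit, "envelope": env, "truth": truth, "calls": calls}


@pytest.fixture(scope="session")
def cohort1000():
    return ncdb.generate_cohort(ncdb.GeneratorConfig(n_patients=1000, seed=COHORT_SEED + 1))


@pytest.fixture()
def tiny_catalog():
    """Two-sign catalog for hand-checkable scoring."""
    return ncdb.SymptomCatalog(
        entries=[
            ncdb.SymptomDefinition(
                symptom_id="clumsiness", label="Clumsiness",
                category="neurological-motor", severity_weight=1.0,
            ),
            ncdb.SymptomDefinition(
                symptom_id="ataxia", label="Ataxia",
                category="neurological-motor", severity_weight=3.0,
            ),
        ],
        version="tiny",
    )


def random_patient(rng: np.random.Generator, catalog: ncdb.SymptomCatalog) -> ncdb.PatientRecord:
    """Random valid patient over ``catalog`` for property tests."""
    onset = round(float(rng.uniform(0, 10)), 1)
    last = round(onset + float(rng.uniform(2, 20)), 1)
    events = []
    for entry in catalog.entries:
        if rng.random() < 0.5:
            events.append(
                ncdb.SymptomEvent(
                    symptom_id=entry.symptom_id,
                    onset_age=min(round(float(rng.uniform(onset, last)), 1), last),
                )
            )
    seizure_ids = {e.symptom_id for e in catalog.entries if e.seizure_domain}
    seizure_onsets = [e.onset_age for e in events if e.symptom_id in seizure_ids]
    return ncdb.PatientRecord(
        patient_id=f"RND{rng.integers(1, 10**9)}",
        age_at_assessment=last,
        age_at_neuro_onset=onset,
        age_at_diagnosis=onset + 1.0,
        age_at_last_visit=last,
        events=events,
        first_seizure_age=min(seizure_onsets) if seizure_onsets else None,
    )
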