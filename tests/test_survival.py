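"""Product-limit estimation: exact-arithmetic oracle, library cross-check,
and the symptom-sequencing layer."""

from fractions import Fraction

import numpy as np
import pytest

import npccdb as ncdb


def km_product_limit_oracle(durations, observed):
    """Brute-force product-limit in exact rational arithmetic.

    Returns (event_times, survival_fractions, median).  Independent of the
    implementation: survival is recomputed from scratch at every distinct
    event time by counting the risk set and events directly.
    """
    times = sorted({d for d, e in zip(durations, observed) if e})
    surv = []
    s = Fraction(1)
    for t in times:
        n = sum(1 for d in durations if d >= t)
        d_events = sum(1 for d, e in zip(durations, observed) if e and d == t)
        s *= 1 - Fraction(d_events, n)
        surv.append(s)
    median = None
    for t, s in zip(times, surv):
        if s <= Fraction(1, 2):
            median = t
            break
    return times, surv, median


def test_no_censoring_closed_form():
    curve = ncdb.km_fit([1, 2, 3], [True, True, True])
    assert curve.times.tolist() == [1, 2, 3]
    assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
    assert curve.median == 2


def test_hand_product_limit_with_censoring():
    curve = ncdb.km_fit([1, 2, 3], [True, False, True])
    assert curve.survival == pytest.approx([2 / 3, 0.0])
    assert curve.median == 3


def test_all_censored_is_flat_with_undefined_median():
    curve = ncdb.km_fit([4, 5, 6], [False, False, False])
    assert curve.times.size == 0
    assert curve.median is None


def test_negative_duration_rejected():
    with pytest.raises(ValueError):
        ncdb.km_fit([-1.0, 2.0], [True, True])
    with pytest.raises(ValueError):
        ncdb.km_fit([], [])


def test_matches_rational_oracle_on_random_small_datasets():
    rng = np.random.default_rng(0)
    for _ in range(300):
        n = int(rng.integers(1, 13))
        durations = rng.integers(0, 8, size=n).astype(float)
        observed = rng.random(n) < 0.7
        curve = ncdb.km_fit(durations, observed)
        times, surv, median = km_product_limit_oracle(durations.tolist(), observed.tolist())
        assert curve.times.tolist() == times
        for s_impl, s_oracle in zip(curve.survival, surv):
            assert s_impl == pytest.approx(float(s_oracle), abs=1e-12)
        assert (curve.median is None) == (median is None)
        if median is not None:
            assert curve.median == pytest.approx(float(median))


def test_agrees_with_lifelines():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(1)
    durations = rng.exponential(5.0, size=80).round(1)
    observed = rng.random(80) < 0.6
    curve = ncdb.km_fit(durations, observed)
    kmf = lifelines.KaplanMeierFitter().fit(durations, observed)
    for t, s in zip(curve.times, curve.survival):
        assert s == pytest.approx(float(kmf.predict(t)), abs=1e-10)
    if curve.median is not None:
        assert curve.median == pytest.approx(float(kmf.median_survival_time_))


def test_no_censoring_limit_equals_one_minus_ecdf():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 10, size=40).round(1)
    curve = ncdb.km_fit(x, np.ones_like(x, dtype=bool))
    for t, s in zip(curve.times, curve.survival):
        assert s == pytest.approx(1.0 - np.mean(x <= t))


def test_censoring_beyond_last_event_location_is_irrelevant():
    """A censored observation beyond the last event contributes only its
    membership in every risk set; *where* beyond the last event it sits
    cannot change the curve."""
    durations = [1.0, 2.0, 3.0, 4.0]
    observed = [True, True, False, True]
    near = ncdb.km_fit(durations + [4.5], observed + [False])
    far = ncdb.km_fit(durations + [99.0], observed + [False])
    assert near.times.tolist() == far.times.tolist()
    assert near.survival == pytest.approx(far.survival)
    assert near.median == far.median


def test_median_ci_contains_median():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(10, 60))
        durations = rng.exponential(5.0, size=n)
        observed = rng.random(n) < 0.7
        curve = ncdb.km_fit(durations, observed)
        if curve.median is None or curve.median_ci is None:
            continue
        lo, hi = curve.median_ci
        if lo is not None:
            assert lo <= curve.median + 1e-12
        if hi is not None:
            assert hi >= curve.median - 1e-12


def test_symptom_onset_curve_single_patient(tiny_catalog):
    patient = ncdb.PatientRecord(
        patient_id="P1", age_at_assessment=10, age_at_neuro_onset=2.0,
        age_at_diagnosis=3.0, age_at_last_visit=10.0,
        events=[ncdb.SymptomEvent(symptom_id="ataxia", onset_age=6.0)],
    )
    cohort = ncdb.Cohort(patients=[patient], catalog=tiny_catalog)
    curve = ncdb.symptom_onset_curve(cohort, "ataxia")
    assert curve.median == pytest.approx(4.0)
    # symptom never manifesting -> all-censored curve
    empty = ncdb.symptom_onset_curve(cohort, "clumsiness")
    assert empty.median is None and empty.times.size == 0
    with pytest.raises(KeyError):
        ncdb.symptom_onset_curve(cohort, "nope")


def test_pre_onset_manifestation_clamped_with_warning(tiny_catalog, caplog):
    patient = ncdb.PatientRecord(
        patient_id="P1", age_at_assessment=10, age_at_neuro_onset=5.0,
        age_at_diagnosis=6.0, age_at_last_visit=10.0,
        events=[ncdb.SymptomEvent(symptom_id="ataxia", onset_age=3.0)],
    )
    cohort = ncdb.Cohort(patients=[patient], catalog=tiny_catalog)
    with caplog.at_level("WARNING"):
        curve = ncdb.symptom_onset_curve(cohort, "ataxia")
    assert curve.median == 0.0
    assert "clamped" in caplog.text


def test_rank_symptoms_order_and_thresholds(cohort500):
    ranks = ncdb.rank_symptoms(
        cohort500, [e.symptom_id for e in cohort500.catalog.entries], min_frequency=0.4
    )
    order = [r.symptom_id for r in ranks]
    # early cognition/coordination signs precede the classical oculomotor and
    # cerebellar signs
    assert order.index("cognitive_impairment") < order.index("vsgp")
    assert order.index("impaired_fine_motor_skills") < order.index("ataxia")
    # nothing manifests in strictly more than 100% of patients
    assert ncdb.rank_symptoms(cohort500, order, min_frequency=1.0) == []
    with pytest.raises(ValueError):
        ncdb.rank_symptoms(cohort500, [], min_frequency=0.4)


def test_rank_symptoms_deterministic_tie_break(tiny_catalog):
    patients = [
        ncdb.PatientRecord(
            patient_id=f"P{i}", age_at_assessment=12, age_at_neuro_onset=2.0,
            age_at_diagnosis=3.0, age_at_last_visit=12.0,
            events=[
                ncdb.SymptomEvent(symptom_id="ataxia", onset_age=5.0),
                ncdb.SymptomEvent(symptom_id="clumsiness", onset_age=5.0),
            ],
        )
        for i in range(4)
    ]
    cohort = ncdb.Cohort(patients=patients, catalog=tiny_catalog)
    ranks = ncdb.rank_symptoms(cohort, ["ataxia", "clumsiness"], min_frequency=0.1)
    # identical medians and frequencies -> alphabetical order
    assert [r.symptom_id for r in ranks] == ["ataxia", "clumsiness"]


def test_onset_relative_to_diagnosis(tiny_catalog):
    patients = [
        ncdb.PatientRecord(
            patient_id="A", age_at_assessment=12, age_at_neuro_onset=1.0,
            age_at_diagnosis=6.0, age_at_last_visit=12.0,
            events=[ncdb.SymptomEvent(symptom_id="ataxia", onset_age=2.0)],
        ),
        ncdb.PatientRecord(
            patient_id="B", age_at_assessment=12, age_at_neuro_onset=1.0,
            age_at_diagnosis=5.0, age_at_last_visit=12.0,
            events=[ncdb.SymptomEvent(symptom_id="ataxia", onset_age=4.0)],
        ),
    ]
    cohort = ncdb.Cohort(patients=patients, catalog=tiny_catalog)
    delta = ncdb.onset_relative_to_diagnosis(cohort, "ataxia")
    assert sorted(delta.deltas.tolist()) == [-4.0, -1.0]
    assert delta.mean == pytest.approx(-2.5)
    with pytest.raises(ValueError):
        ncdb.onset_relative_to_diagnosis(cohort, "clumsiness")


def test_onset_delta_simultaneous_is_zero(tiny_catalog):
    patient = ncdb.PatientRecord(
        patient_id="A", age_at_assessment=12, age_at_neuro_onset=2.0,
        age_at_diagnosis=5.0, age_at_last_visit=12.0,
        events=[ncdb.SymptomEvent(symptom_id="ataxia", onset_age=5.0)],
    )
    cohort = ncdb.Cohort(patients=[patient], catalog=ncdb.default_catalog().subset(["ataxia"]))
    assert ncdb.onset_relative_to_diagnosis(cohort, "ataxia").mean == 0.0
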