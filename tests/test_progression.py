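"""Trend fitting, changepoint detection, classification and exact tests."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, strategies as st

import npccdb as ncdb
from npccdb.progression import Table2x2, fisher_exact
from npccdb.scoring import ScoreTrajectory


def _traj(pid, ys, step=1.0):
    ys = np.asarray(ys, float)
    return ScoreTrajectory(
        patient_id=pid, times=np.arange(len(ys)) * step, scores=ys, grid_step=step
    )


# ---------------------------------------------------------------------------
# cohort trend


def test_cohort_trend_collinear():
    trajs = [_traj(f"P{i}", 2 * np.arange(8) + 1) for i in range(3)]
    fit, env = ncdb.cohort_trend(trajs)
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(1.0)
    assert fit.r_squared == pytest.approx(1.0)
    assert env["sd"].max() == pytest.approx(0.0)


def test_cohort_trend_mean_of_two_lines():
    trajs = [_traj("A", np.arange(8)), _traj("B", 3.0 * np.arange(8))]
    fit, _ = ncdb.cohort_trend(trajs)
    assert fit.slope == pytest.approx(2.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_cohort_trend_requires_two_trajectories():
    with pytest.raises(ValueError):
        ncdb.cohort_trend([_traj("A", np.arange(5))])
    with pytest.raises(ValueError):
        ncdb.cohort_trend(
            [_traj("A", np.arange(5)), _traj("B", np.arange(5), step=0.5)]
        )


def test_cohort_trend_on_default_cohort(cohort500_analysis):
    fit = cohort500_analysis["trend"]
    assert fit.slope > 0
    assert fit.r_squared > 0.9


# ---------------------------------------------------------------------------
# two-segment changepoint


def piecewise(t, bp, s1, s2):
    t = np.asarray(t, float)
    return np.where(t <= bp, s1 * t, s1 * bp + s2 * (t - bp))


def test_two_segment_exact_recovery():
    t = np.arange(13.0)
    fit = ncdb.fit_two_segment((t, piecewise(t, 6, 1, 3)))
    assert fit.breakpoint == 6.0
    assert fit.slope_pre == pytest.approx(1.0, abs=1e-9)
    assert fit.slope_post == pytest.approx(3.0, abs=1e-9)
    assert fit.slope_ratio == pytest.approx(3.0, abs=1e-8)
    assert fit.sse == pytest.approx(0.0, abs=1e-16)


def test_two_segment_degenerate_line():
    t = np.arange(10.0)
    fit = ncdb.fit_two_segment((t, 2.0 * t))
    assert fit.slope_pre == pytest.approx(2.0, abs=1e-9)
    assert fit.slope_post == pytest.approx(2.0, abs=1e-9)
    assert fit.sse == pytest.approx(fit.line_sse, abs=1e-12)


def test_two_segment_insufficient_data_signal():
    t = np.arange(5.0)
    assert ncdb.fit_two_segment((t, t)) is None


def test_two_segment_sse_never_exceeds_line_sse():
    rng = np.random.default_rng(4)
    for _ in range(50):
        n = int(rng.integers(6, 25))
        y = rng.normal(size=n).cumsum()
        y -= y.min()
        fit = ncdb.fit_two_segment((np.arange(n, dtype=float), np.sort(y)))
        if fit is not None:
            assert fit.sse <= fit.line_sse + 1e-9


# ---------------------------------------------------------------------------
# classification


def _flat_envelope(n, mean):
    return pd.DataFrame({"t": np.arange(n, dtype=float), "mean": mean, "sd": 1.0, "n": 10})


def test_classify_fulminant_above_envelope():
    t = np.arange(10.0)
    env = _flat_envelope(10, 2.0 * t)
    call = ncdb.classify_progression(_traj("P", 2.0 * t + 1.0), env)
    assert call.label is ncdb.ProgressionLabel.FULMINANT


def test_classify_accelerated_from_kink():
    t = np.arange(13.0)
    env = _flat_envelope(13, 2.0 * t)  # mean steeper than the pre-segment
    call = ncdb.classify_progression(_traj("P", piecewise(t, 6, 1, 3)), env)
    assert call.label is ncdb.ProgressionLabel.ACCELERATED
    assert call.breakpoint == 6.0
    assert call.slope_ratio == pytest.approx(3.0, abs=1e-8)


def test_classify_steady_on_the_mean_boundary():
    """'Above the mean' is strict: sitting exactly on it is not fulminant."""
    t = np.arange(10.0)
    env = _flat_envelope(10, 2.0 * t)
    call = ncdb.classify_progression(_traj("P", 2.0 * t), env)
    assert call.label is ncdb.ProgressionLabel.STEADY


def test_classify_insufficient_data():
    env = _flat_envelope(4, np.arange(4.0))
    call = ncdb.classify_progression(_traj("P", np.arange(4.0)), env)
    assert call.label is ncdb.ProgressionLabel.INSUFFICIENT_DATA


def test_classify_grid_mismatch_errors():
    env = _flat_envelope(10, np.arange(10.0))
    bad = ScoreTrajectory(
        patient_id="P", times=np.arange(8) * 0.5, scores=np.arange(8.0), grid_step=0.5
    )
    with pytest.raises(ValueError, match="grid"):
        ncdb.classify_progression(bad, env)


def test_classification_invariant_to_weight_rescaling():
    """Progression labels depend only on score ratios and envelope
    comparisons, so scaling every severity weight by a common factor leaves
    every call unchanged."""
    rng = np.random.default_rng(11)
    cohort = ncdb.generate_cohort(ncdb.GeneratorConfig(n_patients=60, seed=77))
    scale = 4.0  # power of two: score sums rescale exactly

    def calls_for(catalog):
        trajs = [
            ncdb.score_trajectory(p, catalog) for p in cohort.neurological_patients
        ]
        _, env = ncdb.cohort_trend(trajs)
        return [ncdb.classify_progression(t, env).label for t in trajs]

    scaled = ncdb.SymptomCatalog(
        entries=[
            e.model_copy(update={"severity_weight": e.severity_weight * scale})
            for e in cohort.catalog.entries
        ],
        version="scaled",
    )
    assert calls_for(cohort.catalog) == calls_for(scaled)


# ---------------------------------------------------------------------------
# Fisher exact test


def fisher_oracle(a, b, c, d):
    """Independent full-enumeration oracle in exact rational arithmetic."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))
    cutoff = probs[a] * Fraction(10**7 + 1, 10**7)
    return sum(p for p in probs.values() if p <= cutoff)


@pytest.mark.parametrize(
    "table, expected",
    [
        ((0, 0, 5, 7), Fraction(1)),
        ((3, 1, 1, 3), Fraction(34, 70)),
        ((5, 0, 0, 5), Fraction(2, 252)),
    ],
)
def test_fisher_known_values(table, expected):
    assert fisher_exact(Table2x2(*table)) == pytest.approx(float(expected), abs=1e-12)


def test_fisher_zero_total_rejected():
    with pytest.raises(ValueError):
        fisher_exact(Table2x2(0, 0, 0, 0))
    with pytest.raises(ValueError):
        Table2x2(-1, 0, 0, 2)


def test_fisher_matches_oracle_small_tables_exhaustive():
    """Exhaustive oracle equivalence for all tables with total <= 12 (the
    full <=30 sweep runs in the acceptance suite)."""
    for n in range(1, 13):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    p = fisher_exact(Table2x2(a, b, c, d))
                    assert p == pytest.approx(float(fisher_oracle(a, b, c, d)), abs=1e-12)


@given(st.tuples(*[st.integers(0, 25)] * 4).filter(lambda t: sum(t) > 0))
def test_fisher_matches_scipy(cells):
    ours = fisher_exact(Table2x2(*cells))
    _, theirs = scipy.stats.fisher_exact(np.array(cells).reshape(2, 2))
    assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# association analyses


def test_seizure_association_requires_seizure_patients():
    cohort = ncdb.generate_cohort(
        ncdb.GeneratorConfig(
            n_patients=30, seed=1, seizure_prevalence=0.0,
            progression_mix=(1.0, 0.0, 0.0),
        )
    )
    with pytest.raises(ValueError, match="seizure"):
        ncdb.seizure_association(cohort)


def test_seizure_association_detects_constructed_link():
    cohort = ncdb.generate_cohort(
        ncdb.GeneratorConfig(
            n_patients=200, seed=5, progression_mix=(0.65, 0.0, 0.35),
            accel_seizure_prob=1.0, frac_pre_neuro_diagnosis=0.0,
            seizure_prevalence=0.35,
        )
    )
    table, p = ncdb.seizure_association(cohort, seed=1)
    assert p < 0.01
    # seizure patients are enriched for the accelerated flag
    assert table.a / (table.a + table.b) > table.c / (table.c + table.d)


def test_si_sensitivity_toy_table():
    rubric = ncdb.RiskIndexRubric(items={"x": 80.0})
    patients = []
    for i in range(12):
        short = i < 6
        patients.append(
            ncdb.PatientRecord(
                patient_id=f"P{i}", age_at_assessment=20, age_at_neuro_onset=1.0,
                age_at_diagnosis=1.0 + (1.0 if short else 8.0), age_at_last_visit=20,
                risk_index_answers={"x": not short},
            )
        )
    cohort = ncdb.Cohort(patients=patients, catalog=ncdb.default_catalog())
    table, p = ncdb.si_sensitivity_vs_duration(cohort, rubric)
    assert (table.a, table.b, table.c, table.d) == (0, 6, 6, 0)
    assert p == pytest.approx(2 / 924)


def test_si_sensitivity_no_association_and_single_stratum():
    rubric = ncdb.RiskIndexRubric(items={"x": 80.0})

    def patient(i, duration):
        return ncdb.PatientRecord(
            patient_id=f"P{i}", age_at_assessment=20, age_at_neuro_onset=1.0,
            age_at_diagnosis=1.0 + duration, age_at_last_visit=20,
            risk_index_answers={"x": True},
        )

    mixed = ncdb.Cohort(
        patients=[patient(i, 1.0 if i < 4 else 8.0) for i in range(8)],
        catalog=ncdb.default_catalog(),
    )
    _, p = ncdb.si_sensitivity_vs_duration(mixed, rubric)
    assert p == 1.0
    short_only = ncdb.Cohort(
        patients=[patient(i, 1.0) for i in range(8)], catalog=ncdb.default_catalog()
    )
    with pytest.raises(ValueError, match="stratum"):
        ncdb.si_sensitivity_vs_duration(short_only, rubric)


# ---------------------------------------------------------------------------
# oxysterol correlation


def _oxy_cohort(levels):
    catalog = ncdb.default_catalog()
    patients = []
    for i, (score_sympt, lvl) in enumerate(levels):
        events = [
            ncdb.SymptomEvent(symptom_id=s, onset_age=2.0) for s in score_sympt
        ]
        patients.append(
            ncdb.PatientRecord(
                patient_id=f"P{i}", age_at_assessment=20, age_at_neuro_onset=1.0,
                age_at_diagnosis=3.0, age_at_last_visit=20, events=events,
                oxysterol_samples=[
                    ncdb.model.OxysterolSample(age=5.0, triol=lvl, seven_kc=lvl * 2)
                ],
            )
        )
    return ncdb.Cohort(patients=patients, catalog=catalog)


def test_oxysterol_regression_recovery():
    cohort = ncdb.generate_cohort(ncdb.GeneratorConfig(n_patients=300, seed=3))
    res = ncdb.oxysterol_correlation(cohort)
    cfg = ncdb.GeneratorConfig()
    assert res.triol.slope == pytest.approx(cfg.oxysterol_triol_slope, abs=0.4)
    assert res.seven_kc.slope == pytest.approx(cfg.oxysterol_7kc_slope, abs=0.8)
    assert res.triol.r_squared > 0.5


def test_oxysterol_constant_levels():
    # scores differ across patients; levels constant -> slope 0, R^2 = 0
    cohort = _oxy_cohort(
        [(["clumsiness"], 50.0), (["clumsiness", "ataxia"], 50.0), (["vsgp"], 50.0)]
    )
    res = ncdb.oxysterol_correlation(cohort)
    assert res.triol.slope == pytest.approx(0.0, abs=1e-9)
    assert res.triol.r_squared == 0.0


def test_oxysterol_cutoff_flags_and_min_patients():
    cohort = _oxy_cohort(
        [(["clumsiness"], 29.0), (["ataxia"], 60.0), (["vsgp"], 80.0)]
    )
    res = ncdb.oxysterol_correlation(cohort)
    row = res.samples[res.samples.patient_id == "P0"].iloc[0]
    assert row.triol == 29.0 and not row.triol_below_cutoff  # 29 > 24.5
    with pytest.raises(ValueError, match="at least 3"):
        ncdb.oxysterol_correlation(
            ncdb.Cohort(patients=cohort.patients[:2], catalog=cohort.catalog)
        )
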