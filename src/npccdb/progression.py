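"""Trajectory trend fitting, progression classification and exact tests.

Three progression phenotypes are distinguished on annual score
trajectories normalised to neurological onset:

* **steady** — gradual accumulation tracking the cohort mean;
* **fulminant** — every annual score strictly above the cohort mean at the
  corresponding time;
* **accelerated** — an initially steady course whose slope later increases
  severalfold, detected by exhaustive two-segment (joined piecewise-linear)
  least squares over candidate breakpoints on the grid, accepted when the
  post/pre slope ratio reaches a threshold and the two-segment fit improves
  on a single line by an F-criterion.

Categorical associations (seizures vs subsequent acceleration; screening-
score sensitivity vs disease duration) are tested with a two-sided Fisher
exact test computed by exact integer hypergeometric enumeration.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .model import Cohort, PatientRecord, RiskCategory, RiskIndexRubric, SymptomCatalog
from .scoring import ScoreTrajectory, compute_score, evaluate_risk_index

# ---------------------------------------------------------------------------
# cohort trend


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r_squared: float


def _ols_line(x: np.ndarray, y: np.ndarray) -> TrendFit:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 1e-300:
        # constant response: no variance to explain
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return TrendFit(slope=float(coef[1]), intercept=float(coef[0]), r_squared=r2)


def cohort_trend(
    trajectories: Sequence[ScoreTrajectory],
    min_coverage: float = 0.2,
) -> tuple[TrendFit, pd.DataFrame]:
    """Mean +/- SD score envelope per grid time and OLS of the mean on time.

    At each grid time the mean is taken over the trajectories still under
    follow-up there.  Times retained by ``min_coverage`` (fraction of
    trajectories still contributing, minimum 2) define the envelope, so the
    sparse late tail of a cohort does not dominate the trend fit.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    steps = {round(t.grid_step, 9) for t in trajectories}
    if len(steps) != 1:
        raise ValueError(f"trajectories on mixed grid steps {sorted(steps)}")
    if any(len(t) == 0 for t in trajectories):
        raise ValueError("empty trajectory grid")
    step = steps.pop()
    max_k = max(len(t) for t in trajectories)
    n_min = max(2, math.ceil(min_coverage * len(trajectories)))
    rows = []
    for k in range(max_k):
        vals = [t.scores[k] for t in trajectories if len(t) > k]
        if len(vals) < n_min:
            break
        arr = np.asarray(vals, float)
        rows.append(
            {
                "t": k * step,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)),
                "n": len(vals),
            }
        )
    if not rows:
        raise ValueError("no grid time has the required coverage")
    env = pd.DataFrame(rows)
    fit = _ols_line(env["t"].to_numpy(), env["mean"].to_numpy())
    return fit, env


# ---------------------------------------------------------------------------
# two-segment changepoint fit


@dataclass(frozen=True)
class TwoSegmentFit:
    breakpoint: float
    slope_pre: float
    slope_post: float
    sse: float
    line_sse: float
    n_points: int

    @property
    def slope_ratio(self) -> Optional[float]:
        if self.slope_pre > 1e-12:
            return self.slope_post / self.slope_pre
        return None


def fit_two_segment(
    trajectory: ScoreTrajectory | tuple[np.ndarray, np.ndarray],
    min_points_per_segment: int = 3,
) -> Optional[TwoSegmentFit]:
    """Continuous two-segment least squares with exhaustive breakpoint search.

    Candidate breakpoints are the grid times leaving at least
    ``min_points_per_segment`` points on each side; for each candidate ``c``
    the model ``y = b0 + b1*t + b2*(t-c)_+`` (segments joined at ``c``) is
    fit by OLS and the sum-of-squares minimiser is returned, together with
    the single-line SSE for model comparison.  Returns ``None`` (an
    insufficient-data signal, not an exception) when the grid is shorter
    than ``2 * min_points_per_segment``.
    """
    if isinstance(trajectory, ScoreTrajectory):
        t, y = trajectory.times, trajectory.scores
    else:
        t, y = (np.asarray(v, float) for v in trajectory)
    n = len(t)
    if min_points_per_segment < 2:
        raise ValueError("min_points_per_segment must be >= 2")
    if n < 2 * min_points_per_segment:
        return None

    line = _ols_line(t, y)
    line_resid = y - (line.intercept + line.slope * t)
    line_sse = float(line_resid @ line_resid)

    best: Optional[tuple[float, float, np.ndarray]] = None  # (sse, c, coef)
    for c in t:
        n_pre = int(np.sum(t <= c))
        n_post = n - n_pre
        if n_pre < min_points_per_segment or n_post < min_points_per_segment - 1:
            continue
        # the joined model shares the breakpoint point between segments, so
        # require min_points on the left and min_points-1 strictly right
        A = np.column_stack([np.ones(n), t, np.maximum(t - c, 0.0)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, float(c), coef)
    if best is None:
        return None
    sse, c, coef = best
    return TwoSegmentFit(
        breakpoint=c,
        slope_pre=float(coef[1]),
        slope_post=float(coef[1] + coef[2]),
        sse=sse,
        line_sse=line_sse,
        n_points=n,
    )


# ---------------------------------------------------------------------------
# progression classification


class ProgressionLabel(str, enum.Enum):
    STEADY = "steady"
    FULMINANT = "fulminant"
    ACCELERATED = "accelerated"
    INSUFFICIENT_DATA = "insufficient_data"


@dataclass(frozen=True)
class ProgressionCall:
    patient_id: str
    label: ProgressionLabel
    breakpoint: Optional[float] = None
    slope_pre: Optional[float] = None
    slope_post: Optional[float] = None
    slope_ratio: Optional[float] = None


def classify_progression(
    trajectory: ScoreTrajectory,
    cohort_envelope: pd.DataFrame,
    accel_ratio_threshold: float = 2.0,
    min_breakpoint_delay: float = 2.0,
    min_points_per_segment: int = 3,
    alpha: float = 0.05,
) -> ProgressionCall:
    """Assign a progression phenotype to one annual trajectory.

    Order of rules: *fulminant* when every annual score from year 1 onward
    strictly exceeds the cohort mean at that time (at least 3 comparable
    years required); otherwise *accelerated* when the two-segment fit
    yields slope_ratio >= threshold, breakpoint >= ``min_breakpoint_delay``
    after onset, and the two-segment model improves the one-line fit at the
    ``alpha`` F-criterion with (1, n-4) degrees of freedom; otherwise
    *steady*.  Short trajectories yield *insufficient_data*.
    """
    env_times = cohort_envelope["t"].to_numpy(float)
    env_means = cohort_envelope["mean"].to_numpy(float)
    env_step = np.diff(env_times)
    if env_step.size and not np.allclose(env_step, trajectory.grid_step):
        raise ValueError("envelope grid step does not match trajectory grid")
    env = dict(zip(np.round(env_times, 9), env_means))

    if len(trajectory) < 2 * min_points_per_segment:
        return ProgressionCall(trajectory.patient_id, ProgressionLabel.INSUFFICIENT_DATA)

    # fulminant: strictly above the collective mean at every comparable year
    comparable = [
        (s, env[rt])
        for t, s in zip(trajectory.times, trajectory.scores)
        if (rt := round(float(t), 9)) in env and t >= trajectory.grid_step - 1e-9
    ]
    if len(comparable) >= 3 and all(s > m for s, m in comparable):
        return ProgressionCall(trajectory.patient_id, ProgressionLabel.FULMINANT)

    fit = fit_two_segment(trajectory, min_points_per_segment)
    if fit is None:
        return ProgressionCall(trajectory.patient_id, ProgressionLabel.INSUFFICIENT_DATA)

    accelerated = False
    ratio = fit.slope_ratio
    if (
        ratio is not None
        and ratio >= accel_ratio_threshold
        and fit.breakpoint >= min_breakpoint_delay
    ):
        dof = fit.n_points - 4
        if dof >= 1:
            if fit.sse <= 1e-10:
                significant = fit.line_sse > 1e-8
            else:
                f_stat = (fit.line_sse - fit.sse) / (fit.sse / dof)
                significant = float(f_dist.sf(f_stat, 1, dof)) < alpha
            accelerated = significant
    if accelerated:
        return ProgressionCall(
            trajectory.patient_id,
            ProgressionLabel.ACCELERATED,
            breakpoint=fit.breakpoint,
            slope_pre=fit.slope_pre,
            slope_post=fit.slope_post,
            slope_ratio=ratio,
        )
    return ProgressionCall(
        trajectory.patient_id,
        ProgressionLabel.STEADY,
        breakpoint=fit.breakpoint,
        slope_pre=fit.slope_pre,
        slope_post=fit.slope_post,
        slope_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# Fisher exact test


@dataclass(frozen=True)
class Table2x2:
    """2x2 contingency table; rows = exposure, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError("table cells must be non-negative integers")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact(table: Table2x2) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    With margins fixed, the probability of a table with first cell ``k`` is
    proportional to the integer weight ``C(r1, k) * C(r2, c1 - k)``; the
    two-sided p-value sums the probabilities of all tables no more likely
    than the observed one (with 1e-7 relative slack for ties), computed in
    exact integer/rational arithmetic.
    """
    if table.total == 0:
        raise ValueError("table total must be positive")
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[table.a]
    # relative slack for float-tie semantics while staying in integers:
    # include k when weights[k] <= w_obs * (1 + 1e-7)
    num = sum(w for w in weights.values() if w * 10**7 <= w_obs * (10**7 + 1))
    p = Fraction(num, math.comb(table.total, c1))
    return min(float(p), 1.0)


# ---------------------------------------------------------------------------
# association analyses


def _window_increments(
    patient: PatientRecord,
    catalog: SymptomCatalog,
    t_center: float,
    window: float,
) -> tuple[float, float]:
    """Cleaned-score increments over (t_center - window, t_center] and
    (t_center, t_center + window] (onset-relative years)."""
    pre = compute_score(patient, catalog, t_center, "cleaned") - compute_score(
        patient, catalog, t_center - window, "cleaned"
    )
    post = compute_score(patient, catalog, t_center + window, "cleaned") - compute_score(
        patient, catalog, t_center, "cleaned"
    )
    return pre, post


def seizure_association(
    cohort: Cohort,
    catalog: Optional[SymptomCatalog] = None,
    window: float = 2.0,
    accel_criterion: float = 2.0,
    seed: int = 0,
) -> tuple[Table2x2, float]:
    """Test whether a first seizure predicts accelerated progression.

    For every patient with a first seizure and at least ``window`` years of
    follow-up on both sides, the seizure-cleaned score increment over the
    ``window`` years after the seizure is compared to the increment over
    the ``window`` years before; the patient is flagged *accelerated* when
    the post/pre ratio reaches ``accel_criterion`` (the pre-increment is
    floored at half the smallest catalog weight so a flat pre-window cannot
    divide by zero).  Each seizure-free patient contributes the same flag
    evaluated at a matched onset-relative time, drawn (seeded) from the
    eligible seizure patients' seizure times compatible with the control's
    follow-up.  Returns the seizure-status x accelerated-flag table and its
    Fisher exact p-value.
    """
    catalog = catalog or cohort.catalog
    eps = catalog.min_weight() / 2.0
    rng = np.random.default_rng(seed)

    seizure_flags: list[bool] = []
    seizure_times: list[float] = []
    for p in cohort.neurological_patients:
        if p.first_seizure_age is None:
            continue
        ts = p.first_seizure_age - p.age_at_neuro_onset
        if ts < window or p.followup_from_onset - ts < window:
            continue
        pre, post = _window_increments(p, catalog, ts, window)
        seizure_flags.append(post / max(pre, eps) >= accel_criterion)
        seizure_times.append(ts)
    if not seizure_times:
        raise ValueError(
            "no seizure patient with sufficient follow-up around the first seizure"
        )

    control_flags: list[bool] = []
    times_arr = np.asarray(seizure_times)
    for p in cohort.neurological_patients:
        if p.first_seizure_age is not None:
            continue
        compatible = times_arr[times_arr + window <= p.followup_from_onset + 1e-9]
        if compatible.size == 0:
            continue
        t_match = float(rng.choice(compatible))
        pre, post = _window_increments(p, catalog, t_match, window)
        control_flags.append(post / max(pre, eps) >= accel_criterion)
    if not control_flags:
        raise ValueError("no seizure-free comparator with sufficient follow-up")

    table = Table2x2(
        a=sum(seizure_flags),
        b=len(seizure_flags) - sum(seizure_flags),
        c=sum(control_flags),
        d=len(control_flags) - sum(control_flags),
    )
    return table, fisher_exact(table)


def si_sensitivity_vs_duration(
    cohort: Cohort,
    rubric: RiskIndexRubric,
    short_threshold: float = 3.0,
) -> tuple[Table2x2, float]:
    """Screening-score sensitivity vs duration of neurological disease.

    Rows: disease duration at diagnosis < ``short_threshold`` (short
    history) vs >= threshold; columns: risk-index category *likely* vs not.
    """
    short_likely = short_not = long_likely = long_not = 0
    for p in cohort.patients:
        dur = p.disease_duration_at_diagnosis
        if dur is None or p.risk_index_answers is None:
            continue
        likely = (
            evaluate_risk_index(p, rubric).category is RiskCategory.LIKELY
        )
        if dur < short_threshold:
            short_likely += likely
            short_not += not likely
        else:
            long_likely += likely
            long_not += not likely
    n_short = short_likely + short_not
    n_long = long_likely + long_not
    if n_short == 0 or n_long == 0:
        raise ValueError("all evaluable patients fall in one duration stratum")
    table = Table2x2(a=short_likely, b=short_not, c=long_likely, d=long_not)
    return table, fisher_exact(table)


# ---------------------------------------------------------------------------
# oxysterol correlation

TRIOL_CUTOFF = 24.5
SEVEN_KC_CUTOFF = 47.5


@dataclass(frozen=True)
class OxysterolCorrelation:
    triol: Optional[TrendFit]
    seven_kc: Optional[TrendFit]
    #: one row per (patient, sample) with below-cut-off flags
    samples: pd.DataFrame
    #: one row per patient: mean score and mean analyte levels
    patient_means: pd.DataFrame


def oxysterol_correlation(
    cohort: Cohort,
    catalog: Optional[SymptomCatalog] = None,
    max_samples_per_patient: int = 3,
) -> OxysterolCorrelation:
    """Linear regression of mean plasma oxysterol levels on mean cumulative
    score, using up to ``max_samples_per_patient`` consecutive samples per
    patient; samples below the screening cut-offs (24.5 ng/mL triol,
    47.5 ng/mL 7-ketocholesterol) are flagged."""
    from .scoring import compute_score_at_age

    catalog = catalog or cohort.catalog
    sample_rows, mean_rows = [], []
    for p in cohort.patients:
        usable = [
            s for s in p.oxysterol_samples if s.age <= p.age_at_last_visit + 1e-9
        ]
        usable = sorted(usable, key=lambda s: s.age)[:max_samples_per_patient]
        if not usable:
            continue
        scores, triols, kcs = [], [], []
        for s in usable:
            score = compute_score_at_age(p, catalog, s.age)
            scores.append(score)
            sample_rows.append(
                {
                    "patient_id": p.patient_id,
                    "age": s.age,
                    "score": score,
                    "triol": s.triol,
                    "seven_kc": s.seven_kc,
                    "triol_below_cutoff": None if s.triol is None else s.triol < TRIOL_CUTOFF,
                    "seven_kc_below_cutoff": None if s.seven_kc is None else s.seven_kc < SEVEN_KC_CUTOFF,
                }
            )
            if s.triol is not None:
                triols.append(s.triol)
            if s.seven_kc is not None:
                kcs.append(s.seven_kc)
        mean_rows.append(
            {
                "patient_id": p.patient_id,
                "mean_score": float(np.mean(scores)),
                "mean_triol": float(np.mean(triols)) if triols else np.nan,
                "mean_seven_kc": float(np.mean(kcs)) if kcs else np.nan,
            }
        )
    means = pd.DataFrame(mean_rows)
    if len(means) < 3:
        raise ValueError("need at least 3 patients with oxysterol samples")

    fits: dict[str, Optional[TrendFit]] = {}
    for col in ("mean_triol", "mean_seven_kc"):
        sub = means.dropna(subset=[col])
        fits[col] = (
            _ols_line(sub["mean_score"].to_numpy(), sub[col].to_numpy())
            if len(sub) >= 3
            else None
        )
    return OxysterolCorrelation(
        triol=fits["mean_triol"],
        seven_kc=fits["mean_seven_kc"],
        samples=pd.DataFrame(sample_rows),
        patient_means=means,
    )
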