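"""Score-trajectory analysis: cohort trend, mean +/- SD envelope, and
per-patient progression classification (steady / fulminant / accelerated)
with two-segment changepoint detection.

Writes results/trajectory_envelope.csv, results/progression_calls.csv and
prints the confusion of calls against the simulation truth.
"""

import argparse
from pathlib import Path

import pandas as pd

import npccdb as ncdb


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort/cohort.json"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = ncdb.read_cohort(args.cohort)
    trajs = {
        p.patient_id: ncdb.score_trajectory(p, cohort.catalog)
        for p in cohort.neurological_patients
    }
    fit, env = ncdb.cohort_trend(list(trajs.values()))
    print(f"cohort trend: score = {fit.slope:.2f} * t + {fit.intercept:.2f}  (R^2 = {fit.r_squared:.3f})")

    calls = {pid: ncdb.classify_progression(t, env) for pid, t in trajs.items()}
    calls_df = pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "label": c.label.value,
                "breakpoint": c.breakpoint,
                "slope_pre": c.slope_pre,
                "slope_post": c.slope_post,
                "slope_ratio": c.slope_ratio,
            }
            for c in calls.values()
        ]
    )
    args.out.mkdir(parents=True, exist_ok=True)
    env.to_csv(args.out / "trajectory_envelope.csv", index=False)
    calls_df.to_csv(args.out / "progression_calls.csv", index=False)
    print("calls:", calls_df.label.value_counts().to_dict())

    try:
        truth = ncdb.truth_table(cohort)
    except ValueError:
        return  # imported cohort: no latent truth to compare against
    merged = calls_df.set_index("patient_id").join(truth, how="inner", rsuffix="_true")
    print("\ncalls vs latent archetype:")
    print(pd.crosstab(merged.archetype, merged.label))
    accel = merged[merged.archetype == "accelerated"]
    if len(accel):
        recall = (accel.label == "accelerated").mean()
        print(f"accelerated recall: {recall:.2f} (n={len(accel)})")


if __name__ == "__main__":
    main()
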