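"""Censored time-to-symptom analysis of the simulated cohort.

Fits Kaplan-Meier onset curves (time from neurological onset, censoring at
last visit) for every scored sign, ranks the frequent signs by median
onset, and measures selected signs' onset relative to diagnosis.  Writes
results/km_ranking.csv and results/onset_vs_diagnosis.csv.

The headline finding this reproduces on synthetic data: less specific
cognition/coordination deficits (median onset ~3.4 y after neurological
onset) precede the classical signs (VSGP/ataxia ~7.4 y) by years.
"""

import argparse
from pathlib import Path

import pandas as pd

import npccdb as ncdb


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort/cohort.json"))
    ap.add_argument("--min-freq", type=float, default=0.4)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = ncdb.read_cohort(args.cohort)
    ids = [e.symptom_id for e in cohort.catalog.entries if e.category.value != "visceral"]
    ranks = ncdb.rank_symptoms(cohort, ids, min_frequency=args.min_freq)
    rank_df = pd.DataFrame(
        [
            {
                "symptom_id": r.symptom_id,
                "km_median": r.median,
                "ci_lo": r.median_ci[0] if r.median_ci else None,
                "ci_hi": r.median_ci[1] if r.median_ci else None,
                "frequency": round(r.frequency, 3),
            }
            for r in ranks
        ]
    )
    args.out.mkdir(parents=True, exist_ok=True)
    rank_df.to_csv(args.out / "km_ranking.csv", index=False)
    print(f"{len(ranks)} signs manifest in > {args.min_freq:.0%} of neurological patients")
    print(rank_df.head(10).to_string(index=False))

    rows = []
    for sid in ("clumsiness", "cognitive_impairment", "impaired_fine_motor_skills",
                "vsgp", "ataxia", "dysarthria"):
        delta = ncdb.onset_relative_to_diagnosis(cohort, sid)
        rows.append({"symptom_id": sid, "mean_delta": round(delta.mean, 2),
                     "sd": round(delta.sd, 2), "median_delta": round(delta.median, 2)})
    delta_df = pd.DataFrame(rows)
    delta_df.to_csv(args.out / "onset_vs_diagnosis.csv", index=False)
    print("\nonset relative to diagnosis (negative = before diagnosis):")
    print(delta_df.to_string(index=False))


if __name__ == "__main__":
    main()
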