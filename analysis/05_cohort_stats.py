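"""Group comparison of imaging metrics on a synthetic cohort.

Draws a two-group cohort (4 treatment effect vs 5 progression) whose
hindered-fraction means mirror the published group statistics
(0.17 +/- 0.02 vs 0.08 +/- 0.03) with all other metrics overlapping,
runs Welch's t per metric with the Bonferroni threshold 0.05/9, and
writes the comparison table.
"""

import argparse
from pathlib import Path

from dbsi import compare_groups, make_cohort
from dbsi.synthetic import CohortSpec


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    records, metrics = make_cohort(CohortSpec(seed=args.seed))
    res = compare_groups(metrics)

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    res.table.to_csv(out / "cohort_comparison.csv")
    metrics.to_csv(out / "cohort_metrics.tsv", sep="\t", index=False)

    print(f"Bonferroni-adjusted threshold: {res.adjusted_alpha:.4f} "
          f"(alpha {res.alpha} over {res.n_metrics} metrics)")
    print(res.table[["mean_treatment_effect", "mean_progression", "t", "p",
                     "significant"]]
          .to_string(float_format=lambda v: f"{v:.4f}"))
    flagged = res.table.index[res.table["significant"]].tolist()
    print(f"metrics flagged significant: {flagged or 'none'}")


if __name__ == "__main__":
    main()
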