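#!/usr/bin/env python
"""Summarize the external-validation metric tables of a fitted grid.

Reads the per-model metric reports written by 03_fit_consensus_grid.py and
condenses them the way the study tables do: the extreme (best/worst) models
per criterion, per evaluation set, at 100% and 95% coverage, plus ability
classification counts.
"""

import argparse
from pathlib import Path

import pandas as pd

MAX_CRITERIA = ["r2", "r0_2", "r0p_2", "rm2_mean", "ccc", "qf2_2"]
MIN_CRITERIA = ["rmse", "mae", "sd_abs_err", "b", "rm2_delta"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--grid", type=Path, default=Path("results/grid"))
    ap.add_argument("--out", type=Path, default=Path("results/validation_summary.tsv"))
    args = ap.parse_args()

    metrics = pd.read_csv(args.grid / "metrics.tsv", sep="\t",
                          dtype={"coverage": str})
    rows = []
    for (set_name, coverage), sub in metrics.groupby(["set", "coverage"]):
        for crit in MAX_CRITERIA + MIN_CRITERIA:
            if crit not in sub.columns:
                continue
            best_is_max = crit in MAX_CRITERIA
            idx = sub[crit].idxmax() if best_is_max else sub[crit].idxmin()
            jdx = sub[crit].idxmin() if best_is_max else sub[crit].idxmax()
            rows.append({
                "set": set_name, "coverage": coverage, "criterion": crit,
                "best_model": sub.loc[idx, "model"],
                "best_value": round(float(sub.loc[idx, crit]), 3),
                "worst_model": sub.loc[jdx, "model"],
                "worst_value": round(float(sub.loc[jdx, crit]), 3),
            })
    summary = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    summary.to_csv(args.out, sep="\t", index=False)

    print(summary.to_string(index=False))
    print("\nability classification counts (test sets):")
    test_rows = metrics[metrics["set"].str.startswith("TS")]
    print(test_rows.groupby(["set", "coverage"])["ability"]
          .value_counts().to_string())
    flagged = test_rows[test_rows["systematic_error"]]
    print(f"\nmodels flagged for systematic error on test sets: "
          f"{sorted(flagged['model'].unique()) or 'none'}")


if __name__ == "__main__":
    main()
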