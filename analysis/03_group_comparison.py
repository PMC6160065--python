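#!/usr/bin/env python
"""Compare the normalized imaging variables between healed and dehisced
wounds (Mann-Whitney U, BH false-discovery-rate adjustment) and the
dehiscence rates between the two hospitals (chi-squared).

Writes results/group_comparison.csv.
"""
from pathlib import Path

import pandas as pd

from woundspec import features as feat
from woundspec import pipeline as pl
from woundspec import stats as st

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    features = pd.read_csv(ROOT / "results" / "features.csv")
    variables = [f"{n}_norm" for n in feat.RAW_INDEX_NAMES]
    table = st.group_comparison_table(features, variables)
    pl.write_csv(ROOT / "results" / "group_comparison.csv", table)

    print("healed vs dehisced, normalized imaging variables "
          "(Mann-Whitney U, BH-adjusted):")
    for _, row in table.iterrows():
        direction = ">" if row["mean_healed"] > row["mean_dehisced"] else "<"
        flag = "*" if row["p_adj"] <= 0.05 else " "
        print(f"  {row['variable']:<18} healed {direction} dehisced  "
              f"p_adj={row['p_adj']:.4g} {flag}")

    # dehiscence rate by hospital (image level)
    counts = (
        features.assign(dehisced=features["outcome"] == "dehisced")
        .groupby("hospital")["dehisced"]
        .agg(["sum", "count"])
    )
    table2x2 = [[int(r["sum"]), int(r["count"] - r["sum"])] for _, r in counts.iterrows()]
    chi2, p = st.chi_squared_2x2(table2x2)
    print(f"dehiscence rate by hospital: chi2={chi2:.3f}, p={p:.3f}")
    print("wrote results/group_comparison.csv")


if __name__ == "__main__":
    main()
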