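#!/usr/bin/env python
"""Step 2 — food-level DSR: annotate the food database and summarize.

Matches every food's ingredient text against the species dictionary,
reports the per-food-group DSR medians (composite dishes are expected on
top), and the Spearman correlations of food DSR with energy density,
GHG emissions and price (Bonferroni-adjusted).
"""

from pathlib import Path

from dsr.foods import (
    annotate_food_table,
    food_level_correlations,
    group_dsr_summary,
    load_food_csv,
    write_food_csv,
)
from dsr.species import load_species_csv
from dsr.stats import correlation_frame
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    dictionary = load_species_csv(DATA / "species.csv")
    foods = annotate_food_table(load_food_csv(DATA / "foods.csv"), dictionary)
    write_food_csv(foods, DATA / "annotated_foods.csv")

    summary = group_dsr_summary(foods)
    frame = pd.DataFrame(
        {
            "foodex2_group": [g.group for g in summary],
            "n": [g.n for g in summary],
            "median_dsr": [g.median for g in summary],
            "q1": [g.q1 for g in summary],
            "q3": [g.q3 for g in summary],
        }
    )
    frame.to_csv(RESULTS / "dsr_by_food_group.csv", index=False)
    print("food-group DSR medians (top 5):")
    print(frame.head(5).to_string(index=False))

    corr = correlation_frame(food_level_correlations(foods, by_group=True))
    corr.to_csv(RESULTS / "food_correlations.csv", index=False)
    overall = corr[corr["x"] == "dsr[all]"]
    print("\nfood-level Spearman correlations with DSR (all foods):")
    print(overall[["y", "rho", "p_adjusted"]].to_string(index=False))


if __name__ == "__main__":
    main()
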