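#!/usr/bin/env python
"""Step 5 — statistical battery on the cohort.

Kruskal-Wallis tests of 4-day DSR across socio-demographic strata
(Bonferroni-adjusted across the family of tests), simple regressions of
DSR on each adherence flag, a multiple regression with demographics,
and the DSR -> NRF8.3 regressions, all written as tidy CSV tables.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from dsr.diary import cohort_results, results_frame
from dsr.foods import load_food_csv
from dsr.pipeline import ADHERENCE_FLAGS, DEMOGRAPHIC_VARS, REFERENCE_LEVELS
from dsr.stats import fit_linear_model, kruskal_wallis_by, regression_frame

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    foods = load_food_csv(DATA / "annotated_foods.csv")
    diaries = pd.read_csv(DATA / "diaries.csv", dtype={"food_code": str})
    participants = pd.read_csv(DATA / "demographics.csv")
    dsr = pd.read_csv(DATA / "participant_dsr.csv")
    quality = pd.read_csv(DATA / "participant_quality.csv")
    merged = dsr.merge(participants, on="participant_id").merge(
        quality, on="participant_id"
    )

    kw = pd.DataFrame(
        [
            dataclasses.asdict(
                kruskal_wallis_by(
                    merged["total_dsr"],
                    merged[var].astype(str),
                    m=len(DEMOGRAPHIC_VARS),
                    grouping=var,
                )
            )
            for var in DEMOGRAPHIC_VARS
        ]
    )
    kw.to_csv(RESULTS / "kruskal_wallis.csv", index=False)
    print("Kruskal-Wallis: DSR across demographic strata")
    print(kw[["grouping", "h_statistic", "df", "p_adjusted"]].to_string(index=False))

    frames = []
    for flag in ADHERENCE_FLAGS:
        if merged[flag].astype(str).nunique() < 2:
            continue
        frames.append(
            regression_frame(
                fit_linear_model(
                    merged["total_dsr"], merged[[flag]].astype(str),
                    outcome_label=f"total_dsr~{flag}",
                    reference_levels={flag: "False"},
                )
            )
        )
    frames.append(
        regression_frame(
            fit_linear_model(
                merged["mean_nrf83"], merged[["total_dsr"]],
                outcome_label="mean_nrf83~total_dsr",
            )
        )
    )
    frames.append(
        regression_frame(
            fit_linear_model(
                merged["mean_nrf83"],
                pd.concat(
                    [
                        merged[["total_dsr"]],
                        merged[["age_group", "income_tertile", "imd_quintile"]].astype(str),
                    ],
                    axis=1,
                ),
                outcome_label="mean_nrf83~total_dsr+demographics",
                reference_levels=REFERENCE_LEVELS,
            )
        )
    )
    reg = pd.concat(frames, ignore_index=True)
    reg.to_csv(RESULTS / "regressions.csv", index=False)
    slope = reg[(reg["outcome"] == "mean_nrf83~total_dsr") & (reg["term"] == "total_dsr")]
    print("\nDSR -> NRF8.3 regression (simple):")
    print(slope[["estimate", "se", "t_value", "p_value"]].to_string(index=False))


if __name__ == "__main__":
    main()
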