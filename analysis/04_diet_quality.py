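#!/usr/bin/env python
"""Step 4 — diet quality: NRF8.3 per 100 kcal and guideline adherence.

Scores every participant's diet with the energy-weighted NRF8.3 index,
builds daily intake summaries and classifies adherence to the seven UK
guidelines plus the >=60%-processed-energy flag.
"""

from pathlib import Path

import pandas as pd

from dsr.diary import validate_cohort
from dsr.foods import load_food_csv
from dsr.quality import cohort_quality_frame, load_reference_values

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"

FLAGS = ["sfa_ok", "free_sugars_ok", "red_meat_ok", "salt_ok", "fibre_ok",
         "fv_ok", "fish_ok", "all_ok", "high_processed_eater"]


def main() -> None:
    foods = load_food_csv(DATA / "annotated_foods.csv")
    diaries = pd.read_csv(DATA / "diaries.csv", dtype={"food_code": str})
    rv = load_reference_values()
    included = validate_cohort(diaries)
    quality = cohort_quality_frame(diaries, foods, rv, included)
    quality.to_csv(DATA / "participant_quality.csv", index=False)

    rates = quality[FLAGS].mean().rename("adherence_rate").to_frame()
    rates.to_csv(RESULTS / "adherence_rates.csv")
    print(f"scored {len(quality)} participants")
    print("\nadherence rates:")
    print(rates.to_string())
    print(
        f"\nmean NRF8.3 per 100 kcal: {quality['mean_nrf83'].mean():.1f} "
        f"(sd {quality['mean_nrf83'].std():.1f})"
    )


if __name__ == "__main__":
    main()
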