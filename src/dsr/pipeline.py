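"""End-to-end pipeline: read the three input tables, run every analysis
stage, write tidy CSV outputs and a reproducibility manifest.

Inputs are UTF-8 CSVs with header rows: a species dictionary, a food
table, diaries (participant_id, day, food_code, grams) and demographics.
Outputs land in one directory; re-running with identical inputs and
configuration reproduces byte-identical files (the manifest records the
configuration hash and seed, never wall-clock time).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diary import (
    cohort_accumulation_summary,
    cohort_results,
    results_frame,
    two_day_coverage,
    validate_cohort,
)
from .foods import (
    annotate_food_table,
    food_level_correlations,
    group_dsr_summary,
    load_food_csv,
    write_food_csv,
)
from .quality import cohort_quality_frame, load_reference_values
from .species import load_species_csv
from .stats import (
    correlation_frame,
    fit_linear_model,
    kruskal_wallis_by,
    regression_frame,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

DEMOGRAPHIC_VARS = (
    "age_group",
    "sex",
    "ethnicity",
    "bmi_category",
    "imd_quintile",
    "income_tertile",
    "marital_status",
)

ADHERENCE_FLAGS = (
    "sfa_ok",
    "free_sugars_ok",
    "red_meat_ok",
    "salt_ok",
    "fibre_ok",
    "fv_ok",
    "fish_ok",
    "high_processed_eater",
)

REFERENCE_LEVELS = {
    "age_group": "children",
    "income_tertile": "1",
    "imd_quintile": "1",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and switches for one pipeline run."""

    species_csv: str
    food_csv: str
    diaries_csv: str
    demographics_csv: str
    out_dir: str
    reference_values: str | None = None
    overrides_csv: str | None = None
    include_three_day_totals: bool = True
    sugar_kcal_per_g: float = 4.0
    nrf_weighted: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def digest(self) -> str:
        # out_dir is where the manifest itself lives; identical analyses
        # written to different directories share a digest
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _require(path: str, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {path}")
    return p


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run annotation, accumulation, quality and statistics end to end.

    Returns a mapping of output name to written path.  Missing food
    codes in the diaries are reported exhaustively before aborting.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dictionary = load_species_csv(
        _require(config.species_csv, "species dictionary"),
        overrides_path=config.overrides_csv,
    )
    foods = load_food_csv(_require(config.food_csv, "food table"))
    diaries = pd.read_csv(
        _require(config.diaries_csv, "diaries"), dtype={"food_code": str}
    )
    for col in ("participant_id", "day", "food_code", "grams"):
        if col not in diaries.columns:
            raise ValueError(f"diaries missing column {col!r}")
    participants = pd.read_csv(_require(config.demographics_csv, "demographics"))
    rv = load_reference_values(config.reference_values)

    unknown = sorted(
        set(diaries["food_code"].astype(str)) - set(foods["food_code"].astype(str))
    )
    if unknown:
        raise KeyError(f"diaries reference {len(unknown)} unknown food codes: {unknown}")

    outputs: dict[str, Path] = {}

    def write(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        outputs[name] = path

    # 1. food level
    annotated = annotate_food_table(foods, dictionary)
    write_food_csv(annotated, out_dir / "annotated_foods.csv")
    outputs["annotated_foods"] = out_dir / "annotated_foods.csv"
    for level in ("group", "subgroup"):
        summary = group_dsr_summary(annotated, level)
        write(
            f"dsr_by_{level}",
            pd.DataFrame(
                {
                    f"foodex2_{level}": [g.group for g in summary],
                    "n": [g.n for g in summary],
                    "median_dsr": [g.median for g in summary],
                    "q1": [g.q1 for g in summary],
                    "q3": [g.q3 for g in summary],
                }
            ),
        )
    write(
        "food_correlations",
        correlation_frame(food_level_correlations(annotated, by_group=True)),
    )

    # 2. participant accumulation
    included = validate_cohort(diaries, participants)
    results = cohort_results(diaries, annotated, participants)
    write("participant_dsr", results_frame(results))
    write(
        "accumulation_summary",
        cohort_accumulation_summary(
            results, include_three_day_totals=config.include_three_day_totals
        ),
    )

    # 3. diet quality and adherence
    quality = cohort_quality_frame(
        diaries,
        annotated,
        rv,
        included,
        sugar_kcal_per_g=config.sugar_kcal_per_g,
        nrf_weighted=config.nrf_weighted,
    )
    write("participant_quality", quality)

    # 4. statistics
    merged = results_frame(results).merge(
        participants, on="participant_id", how="inner"
    )
    merged = merged.merge(quality, on="participant_id", how="inner")
    kw_rows = []
    for var in DEMOGRAPHIC_VARS:
        if merged[var].astype(str).nunique() < 2 or merged["total_dsr"].nunique() < 2:
            logger.info("skipping Kruskal-Wallis for %s (insufficient variation)", var)
            continue
        res = kruskal_wallis_by(
            merged["total_dsr"], merged[var].astype(str),
            m=len(DEMOGRAPHIC_VARS), grouping=var,
        )
        kw_rows.append(dataclasses.asdict(res))
    write("kruskal_wallis", pd.DataFrame(kw_rows))

    def try_fit(outcome, predictors, label, refs=None):
        try:
            return regression_frame(
                fit_linear_model(
                    outcome, predictors, outcome_label=label, reference_levels=refs
                )
            )
        except ValueError as exc:
            logger.info("skipping regression %s: %s", label, exc)
            return None

    reg_frames = []
    for flag in ADHERENCE_FLAGS:
        if merged[flag].astype(str).nunique() < 2:
            logger.info("skipping regression on %s (constant flag)", flag)
            continue
        reg_frames.append(
            try_fit(
                merged["total_dsr"], merged[[flag]].astype(str),
                f"total_dsr~{flag}", {flag: "False"},
            )
        )
    reg_frames.append(
        try_fit(
            merged["total_dsr"],
            merged[["age_group", "income_tertile", "imd_quintile", *ADHERENCE_FLAGS]].astype(str),
            "total_dsr_multiple",
            {**REFERENCE_LEVELS, **{f: "False" for f in ADHERENCE_FLAGS}},
        )
    )
    reg_frames.append(
        try_fit(merged["mean_nrf83"], merged[["total_dsr"]], "mean_nrf83")
    )
    reg_frames.append(
        try_fit(
            merged["mean_nrf83"],
            pd.concat(
                [
                    merged[["total_dsr"]],
                    merged[["age_group", "income_tertile", "imd_quintile"]].astype(str),
                ],
                axis=1,
            ),
            "mean_nrf83_adjusted",
            REFERENCE_LEVELS,
        )
    )
    reg_frames = [f for f in reg_frames if f is not None]
    write(
        "regressions",
        pd.concat(reg_frames, ignore_index=True) if reg_frames else pd.DataFrame(),
    )

    coverage = two_day_coverage(results)
    manifest = {
        "package_version": __version__,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"
        },
        "config_digest": config.digest(),
        "n_participants_included": len(included),
        "two_day_coverage": coverage,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path
    logger.info("pipeline wrote %d outputs to %s", len(outputs), out_dir)
    return outputs
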