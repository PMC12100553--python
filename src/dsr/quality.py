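"""Diet quality: NRF8.3 nutrient-density scoring and guideline adherence.

The Nutrient Rich Food 8.3 index scores a food per 418 kJ (100 kcal):
the sum over eight qualifying nutrients of their percent daily value per
100 kcal, each capped at 100, minus the (uncapped) percent maximum
reference value per 100 kcal of three nutrients to limit (saturated fat,
free sugars, sodium).  Participant-level diet quality is the
energy-weighted mean of food-level scores over everything consumed.

Guideline adherence uses the UK cut-offs with the printed comparison
directions kept strict: saturated fat < 11% of energy, free sugars < 5%
of energy, red meat < 70 g/day, salt < 6 g/day, fibre > 30 g/day, fruit
and vegetables > 400 g/day, fish > 280 g/week.  Participants taking
>= 60% of energy from NOVA class 3-4 foods are "high processed food
eaters".
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .foods import NutrientProfile

__all__ = [
    "ReferenceValues",
    "IntakeSummary",
    "AdherenceProfile",
    "GUIDELINE_CUTOFFS",
    "load_reference_values",
    "nrf83_score",
    "participant_mean_nrf",
    "intake_summary",
    "classify_adherence",
    "cohort_quality_frame",
]

SFA_KCAL_PER_G = 9.0
FREE_SUGARS_KCAL_PER_G = 4.0       # UK-convention alternative: 3.75
SALT_PER_SODIUM = 2.5 / 1000.0     # g salt per mg sodium
UPF_NOVA_CLASSES = (3, 4)

GUIDELINE_CUTOFFS = {
    "sfa_energy_pct": ("<", 11.0),
    "free_sugars_energy_pct": ("<", 5.0),
    "red_meat_g_per_day": ("<", 70.0),
    "salt_g_per_day": ("<", 6.0),
    "fibre_g_per_day": (">", 30.0),
    "fv_g_per_day": (">", 400.0),
    "fish_g_per_week": (">", 280.0),
}
HIGH_PROCESSED_CUTOFF = 60.0  # >= , % of energy from NOVA 3-4


@dataclass(frozen=True)
class ReferenceValues:
    """DV table for qualifying nutrients and MRV for nutrients to limit."""

    qualifying: Mapping[str, float]
    limiting: Mapping[str, float]

    def __post_init__(self) -> None:
        for table in (self.qualifying, self.limiting):
            for k, v in table.items():
                if v <= 0:
                    raise ValueError(f"reference value {k} must be > 0")


def load_reference_values(path: str | Path | None = None) -> ReferenceValues:
    """Load the DV/MRV table from YAML (packaged default if no path)."""
    if path is None:
        ref = resources.files("dsr.data") / "nrf_reference_values.yaml"
        with resources.as_file(ref) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return ReferenceValues(
        qualifying=dict(raw["qualifying"]), limiting=dict(raw["limiting"])
    )


def nrf83_score(profile: NutrientProfile, rv: ReferenceValues) -> float:
    """NRF8.3 score of one food per 100 kcal.

    amount-per-100 kcal = amount-per-100 g * (100 / energy_kcal-per-100 g);
    qualifying contributions are min(100, 100 * amount / DV), limiting
    contributions 100 * amount / MRV, uncapped.  Zero-energy foods have
    no defined per-100 kcal basis and raise ``ValueError``.
    """
    if profile.energy_kcal <= 0:
        raise ValueError("NRF8.3 per 100 kcal undefined for zero-energy food")
    scale = 100.0 / profile.energy_kcal
    score = 0.0
    for nutrient, dv in rv.qualifying.items():
        amount = getattr(profile, nutrient) * scale
        score += min(100.0, 100.0 * amount / dv)
    for nutrient, mrv in rv.limiting.items():
        amount = getattr(profile, nutrient) * scale
        score -= 100.0 * amount / mrv
    return score


def _profile_from_row(row: pd.Series) -> NutrientProfile:
    kwargs = {f.name: float(row[f.name]) for f in dc_fields(NutrientProfile)}
    return NutrientProfile(**kwargs)


def food_table_nrf(foods: pd.DataFrame, rv: ReferenceValues) -> pd.Series:
    """NRF8.3 per food row; NaN where energy is zero (score undefined)."""
    out = []
    for _, row in foods.iterrows():
        if row["energy_kcal"] <= 0:
            out.append(np.nan)
        else:
            out.append(nrf83_score(_profile_from_row(row), rv))
    return pd.Series(out, index=foods.index, name="nrf83")


def participant_mean_nrf(
    participant_diary: pd.DataFrame,
    foods: pd.DataFrame,
    rv: ReferenceValues,
    weighted: bool = True,
) -> float:
    """Participant-level NRF8.3: mean of food scores across consumptions.

    The default weights each consumption by the energy it contributes
    (kcal), so the score is per 100 kcal of the whole diet; ``weighted=
    False`` averages food scores unweighted.  Zero-energy consumptions
    carry no weight and are ignored in either mode.
    """
    merged = participant_diary.merge(
        foods[["food_code", *_NUTRIENT_FIELDS]], on="food_code", how="left"
    )
    if merged["energy_kcal"].isna().any():
        missing = sorted(
            merged.loc[merged["energy_kcal"].isna(), "food_code"].astype(str).unique()
        )
        raise KeyError(f"unknown food codes in diary: {missing}")
    scores = []
    weights = []
    for _, row in merged.iterrows():
        if row["energy_kcal"] <= 0:
            continue
        scores.append(nrf83_score(_profile_from_row(row), rv))
        weights.append(row["grams"] / 100.0 * row["energy_kcal"])
    if not scores:
        raise ValueError("participant consumed no energy-bearing foods")
    if weighted:
        return float(np.average(scores, weights=weights))
    return float(np.mean(scores))


_NUTRIENT_FIELDS = [f.name for f in dc_fields(NutrientProfile)]


@dataclass(frozen=True)
class IntakeSummary:
    """Daily-average intake quantities feeding the adherence cut-offs."""

    participant_id: str
    energy_kcal_per_day: float
    sfa_energy_pct: float
    free_sugars_energy_pct: float
    red_meat_g_per_day: float
    salt_g_per_day: float
    fibre_g_per_day: float
    fv_g_per_day: float
    fish_g_per_week: float
    upf_energy_pct: float

    def __post_init__(self) -> None:
        for pct in ("sfa_energy_pct", "free_sugars_energy_pct", "upf_energy_pct"):
            v = getattr(self, pct)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{pct}={v} outside [0, 100]")


@dataclass(frozen=True)
class AdherenceProfile:
    """Boolean guideline flags; ``all_ok`` is their conjunction."""

    participant_id: str
    sfa_ok: bool
    free_sugars_ok: bool
    red_meat_ok: bool
    salt_ok: bool
    fibre_ok: bool
    fv_ok: bool
    fish_ok: bool
    all_ok: bool
    high_processed_eater: bool

    def __post_init__(self) -> None:
        expected = (
            self.sfa_ok
            and self.free_sugars_ok
            and self.red_meat_ok
            and self.salt_ok
            and self.fibre_ok
            and self.fv_ok
            and self.fish_ok
        )
        if self.all_ok != expected:
            raise ValueError("all_ok must be the conjunction of the seven flags")


def intake_summary(
    participant_diary: pd.DataFrame,
    foods: pd.DataFrame,
    sugar_kcal_per_g: float = FREE_SUGARS_KCAL_PER_G,
) -> IntakeSummary:
    """Daily-average intakes for one participant's completed days.

    Energy percentages use 9 kcal/g for saturated fat and the configured
    factor for free sugars; salt is sodium * 2.5 / 1000; the fish weekly
    equivalent is mean daily fish grams * 7; the processed-energy share
    is the energy fraction from NOVA classes 3 and 4.
    """
    pid = str(participant_diary["participant_id"].iloc[0])
    cols = [
        "food_code",
        "energy_kcal",
        "saturated_fat_g",
        "free_sugars_g",
        "sodium_mg",
        "fibre_g",
        "red_meat_g_per_100g",
        "fish_g_per_100g",
        "fv_g_per_100g",
        "nova_class",
    ]
    merged = participant_diary.merge(foods[cols], on="food_code", how="left")
    if merged["energy_kcal"].isna().any():
        missing = sorted(
            merged.loc[merged["energy_kcal"].isna(), "food_code"].astype(str).unique()
        )
        raise KeyError(f"unknown food codes in diary: {missing}")
    n_days = merged["day"].nunique()
    factor = merged["grams"] / 100.0
    energy = float((factor * merged["energy_kcal"]).sum())
    if energy <= 0:
        raise ValueError(f"participant {pid}: no energy intake recorded")
    sfa_g = float((factor * merged["saturated_fat_g"]).sum())
    sugar_g = float((factor * merged["free_sugars_g"]).sum())
    sodium_mg = float((factor * merged["sodium_mg"]).sum())
    fibre_g = float((factor * merged["fibre_g"]).sum())
    red_meat_g = float((factor * merged["red_meat_g_per_100g"]).sum())
    fish_g = float((factor * merged["fish_g_per_100g"]).sum())
    fv_g = float((factor * merged["fv_g_per_100g"]).sum())
    upf_energy = float(
        (factor * merged["energy_kcal"])[merged["nova_class"].isin(UPF_NOVA_CLASSES)].sum()
    )
    return IntakeSummary(
        participant_id=pid,
        energy_kcal_per_day=energy / n_days,
        sfa_energy_pct=min(100.0, 100.0 * sfa_g * SFA_KCAL_PER_G / energy),
        free_sugars_energy_pct=min(100.0, 100.0 * sugar_g * sugar_kcal_per_g / energy),
        red_meat_g_per_day=red_meat_g / n_days,
        salt_g_per_day=sodium_mg * SALT_PER_SODIUM / n_days,
        fibre_g_per_day=fibre_g / n_days,
        fv_g_per_day=fv_g / n_days,
        fish_g_per_week=fish_g / n_days * 7.0,
        upf_energy_pct=100.0 * upf_energy / energy,
    )


def classify_adherence(summary: IntakeSummary) -> AdherenceProfile:
    """Apply the guideline cut-offs with strict comparisons as printed."""
    flags = {}
    for field_name, (op, cutoff) in GUIDELINE_CUTOFFS.items():
        value = getattr(summary, field_name)
        flags[field_name] = value < cutoff if op == "<" else value > cutoff
    seven = [
        flags["sfa_energy_pct"],
        flags["free_sugars_energy_pct"],
        flags["red_meat_g_per_day"],
        flags["salt_g_per_day"],
        flags["fibre_g_per_day"],
        flags["fv_g_per_day"],
        flags["fish_g_per_week"],
    ]
    return AdherenceProfile(
        participant_id=summary.participant_id,
        sfa_ok=flags["sfa_energy_pct"],
        free_sugars_ok=flags["free_sugars_energy_pct"],
        red_meat_ok=flags["red_meat_g_per_day"],
        salt_ok=flags["salt_g_per_day"],
        fibre_ok=flags["fibre_g_per_day"],
        fv_ok=flags["fv_g_per_day"],
        fish_ok=flags["fish_g_per_week"],
        all_ok=all(seven),
        high_processed_eater=summary.upf_energy_pct >= HIGH_PROCESSED_CUTOFF,
    )


def cohort_quality_frame(
    diaries: pd.DataFrame,
    foods: pd.DataFrame,
    rv: ReferenceValues,
    included_ids: list[str],
    sugar_kcal_per_g: float = FREE_SUGARS_KCAL_PER_G,
    nrf_weighted: bool = True,
) -> pd.DataFrame:
    """Per-participant intake summary, adherence flags and mean NRF8.3."""
    rows = []
    diaries = diaries[diaries["participant_id"].astype(str).isin(set(included_ids))]
    for pid, sub in diaries.groupby(diaries["participant_id"].astype(str), sort=True):
        s = intake_summary(sub, foods, sugar_kcal_per_g=sugar_kcal_per_g)
        a = classify_adherence(s)
        nrf = participant_mean_nrf(sub, foods, rv, weighted=nrf_weighted)
        row = {**s.__dict__, **{k: v for k, v in a.__dict__.items() if k != "participant_id"}}
        row["mean_nrf83"] = nrf
        rows.append(row)
    return pd.DataFrame(rows)
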