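"""Food-item records, food-level DSR annotation and food-level analyses.

The food database mirrors an expanded national nutrient databank: one row
per food or drink code, carrying a FoodEx2-style group and subgroup, the
raw ingredient text, nutrients per 100 g, a NOVA processing class (1-4),
farm-to-fork greenhouse-gas emissions per kg, retail price per 100 g and
gram contributions towards the red-meat, fish and fruit-and-veg
guidelines.  The in-memory container is a pandas DataFrame; species sets
are serialized as semicolon-delimited species ids in CSV output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .species import SpeciesDictionary, match_species
from .stats import CorrelationResult, spearman_bonferroni

logger = logging.getLogger(__name__)

__all__ = [
    "NUTRIENT_COLUMNS",
    "FOOD_COLUMNS",
    "NutrientProfile",
    "GroupSummary",
    "annotate_food",
    "annotate_food_table",
    "group_dsr_summary",
    "food_level_correlations",
    "load_food_csv",
    "write_food_csv",
]

NUTRIENT_COLUMNS = (
    "energy_kcal",
    "energy_kj",
    "protein_g",
    "fibre_g",
    "vitamin_a_ug",
    "vitamin_c_mg",
    "vitamin_e_mg",
    "calcium_mg",
    "iron_mg",
    "potassium_mg",
    "magnesium_mg",
    "saturated_fat_g",
    "free_sugars_g",
    "sodium_mg",
)

FOOD_COLUMNS = (
    "food_code",
    "description",
    "foodex2_group",
    "foodex2_subgroup",
    "ingredients_text",
    *NUTRIENT_COLUMNS,
    "nova_class",
    "ghg_per_kg",
    "price_per_100g",
    "red_meat_g_per_100g",
    "fish_g_per_100g",
    "fv_g_per_100g",
)


@dataclass(frozen=True)
class NutrientProfile:
    """Nutrients per 100 g of food (energy in kcal and kJ)."""

    energy_kcal: float
    energy_kj: float
    protein_g: float = 0.0
    fibre_g: float = 0.0
    vitamin_a_ug: float = 0.0
    vitamin_c_mg: float = 0.0
    vitamin_e_mg: float = 0.0
    calcium_mg: float = 0.0
    iron_mg: float = 0.0
    potassium_mg: float = 0.0
    magnesium_mg: float = 0.0
    saturated_fat_g: float = 0.0
    free_sugars_g: float = 0.0
    sodium_mg: float = 0.0

    def __post_init__(self) -> None:
        for name in NUTRIENT_COLUMNS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.energy_kcal > 0:
            ratio = self.energy_kj / (4.184 * self.energy_kcal)
            if not (0.98 <= ratio <= 1.02):
                raise ValueError(
                    f"energy_kj={self.energy_kj} inconsistent with "
                    f"energy_kcal={self.energy_kcal} (kJ/kcal ratio off by >2%)"
                )


@dataclass(frozen=True)
class GroupSummary:
    """Distribution of food-level DSR within one food group."""

    group: str
    n: int
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")
        if self.n < 1:
            raise ValueError("empty group")


def annotate_food(ingredients_text: str, dictionary: SpeciesDictionary) -> tuple[frozenset[str], int]:
    """Match one food's ingredient text; returns (species_set, dsr)."""
    s = frozenset(match_species(ingredients_text, dictionary))
    return s, len(s)


def annotate_food_table(
    foods: pd.DataFrame, dictionary: SpeciesDictionary, warn_empty: bool = True
) -> pd.DataFrame:
    """Annotate every food with its species set and DSR.

    Adds/overwrites columns ``species_set`` (frozenset of species ids) and
    ``dsr``.  Foods that match no species keep dsr = 0 and are reported
    with a single warning (not an error): genuinely species-free items
    such as water and salt are expected.
    """
    foods = foods.copy()
    sets = [
        frozenset(match_species(t if isinstance(t, str) else "", dictionary))
        for t in foods["ingredients_text"]
    ]
    foods["species_set"] = sets
    foods["dsr"] = [len(s) for s in sets]
    n_empty = int((foods["dsr"] == 0).sum())
    if warn_empty and n_empty:
        logger.warning(
            "%d of %d foods matched no species (dsr=0)", n_empty, len(foods)
        )
    return foods


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    # linear-interpolation quantiles (numpy default, R type 7)
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return float(q1), float(med), float(q3)


def group_dsr_summary(
    foods: pd.DataFrame, level: Literal["group", "subgroup"] = "group"
) -> list[GroupSummary]:
    """Median (Q1, Q3) food-level DSR per FoodEx2 group or subgroup.

    Sorted by median descending, ties broken alphabetically by label.
    Quartiles use linear interpolation (R type-7), the package-wide rule.
    """
    if "dsr" not in foods.columns:
        raise ValueError("foods must be annotated (missing 'dsr' column)")
    col = "foodex2_group" if level == "group" else "foodex2_subgroup"
    out = []
    for label, sub in foods.groupby(col, sort=True):
        q1, med, q3 = _quartiles(sub["dsr"].to_numpy(dtype=float))
        out.append(GroupSummary(group=str(label), n=len(sub), median=med, q1=q1, q3=q3))
    out.sort(key=lambda g: (-g.median, g.group))
    return out


_CORRELATION_VARS = {
    "energy_density": "energy_kcal",  # kcal per 100 g
    "ghg": "ghg_per_kg",
    "price": "price_per_100g",
}


def food_level_correlations(
    foods: pd.DataFrame,
    variables: Sequence[str] = ("energy_density", "ghg", "price"),
    by_group: bool = False,
    m: int | None = None,
) -> list[CorrelationResult]:
    """Spearman correlations of food DSR with food characteristics.

    Energy density is kcal per 100 g (the per-100 g nutrient convention);
    price is GBP per 100 g; GHG is g CO2-eq per kg.  P-values are
    Bonferroni-adjusted with family size ``m`` = number of tests in this
    call unless given explicitly.  Raises on a constant variable.
    """
    unknown = set(variables) - set(_CORRELATION_VARS)
    if unknown:
        raise ValueError(f"unknown variables: {sorted(unknown)}")
    groups: list[tuple[str, pd.DataFrame]] = [("all", foods)]
    if by_group:
        groups += [(str(g), sub) for g, sub in foods.groupby("foodex2_group", sort=True)]
    pairs = []
    labels = []
    for gname, sub in groups:
        if len(sub) < 3:
            continue
        x = sub["dsr"].to_numpy(dtype=float)
        for var in variables:
            y = sub[_CORRELATION_VARS[var]].to_numpy(dtype=float)
            if np.isnan(y).any() or np.isnan(x).any():
                raise ValueError(f"missing values in {var} ({gname})")
            if gname != "all" and (np.ptp(x) == 0 or np.ptp(y) == 0):
                # a degenerate stratum in the by-group sweep (e.g. every
                # oil has dsr 1): skip it rather than abort the sweep
                logger.info("skipping correlation %s in %s: constant", var, gname)
                continue
            pairs.append((x, y))
            labels.append((f"dsr[{gname}]", var))
    family = m if m is not None else len(pairs)
    return spearman_bonferroni(pairs, m=family, labels=labels)


def load_food_csv(path: str | Path) -> pd.DataFrame:
    """Read a food table CSV, validating required columns.

    If an annotated table is read back, the ``species_set`` column
    (semicolon-delimited ids) is deserialized to frozensets.
    """
    foods = pd.read_csv(path, dtype={"food_code": str})
    missing = set(FOOD_COLUMNS) - set(foods.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not foods["food_code"].is_unique:
        dup = foods["food_code"][foods["food_code"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate food_code {dup!r}")
    if not foods["nova_class"].isin([1, 2, 3, 4]).all():
        raise ValueError(f"{path}: nova_class must be in 1..4")
    if "species_set" in foods.columns:
        foods["species_set"] = [
            frozenset(s.split(";")) if isinstance(s, str) and s else frozenset()
            for s in foods["species_set"]
        ]
        foods["dsr"] = [len(s) for s in foods["species_set"]]
    return foods


def write_food_csv(foods: pd.DataFrame, path: str | Path) -> None:
    """Write a (possibly annotated) food table; species sets as sorted
    semicolon-delimited ids so output is byte-reproducible."""
    out = foods.copy()
    out = out.drop(columns=[c for c in out.columns if c.startswith("_")])
    if "species_set" in out.columns:
        out["species_set"] = [";".join(sorted(s)) for s in out["species_set"]]
    out.to_csv(path, index=False)
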