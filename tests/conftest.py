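"""Shared fixtures: a small hand-built species dictionary, a five-food
database and a three-participant diary whose expected outputs are fully
hand-computed in the tests."""

from __future__ import annotations

import pandas as pd
import pytest

from dsr.foods import FOOD_COLUMNS
from dsr.species import OverrideRule, SpeciesRecord, compile_index


@pytest.fixture(scope="session")
def toy_records() -> list[SpeciesRecord]:
    return [
        SpeciesRecord("wheat", "Triticum aestivum", ("wheat", "durum wheat", "wheat flour"), "cereal_grain"),
        SpeciesRecord("tomato", "Solanum lycopersicum", ("tomato", "tomato puree"), "vegetable"),
        SpeciesRecord("cattle", "Bos taurus", ("beef", "milk", "cheese", "butter"), "animal_terrestrial"),
        SpeciesRecord("apple", "Malus domestica", ("apple",), "fruit"),
        SpeciesRecord("pineapple", "Ananas comosus", ("pineapple",), "fruit"),
        SpeciesRecord("basil", "Ocimum basilicum", ("basil",), "herb_spice"),
        SpeciesRecord("salmon", "Salmo salar", ("salmon", "atlantic salmon"), "fish_and_aquatic"),
        SpeciesRecord("vanilla", "Vanilla planifolia", ("vanilla",), "herb_spice"),
    ]


@pytest.fixture(scope="session")
def toy_dict(toy_records):
    return compile_index(toy_records)


@pytest.fixture(scope="session")
def toy_dict_with_overrides(toy_records):
    return compile_index(
        toy_records,
        overrides=(
            OverrideRule("wholemeal", "wheat", "include"),
            OverrideRule("lactose free", "cattle", "exclude"),
        ),
    )


def _food_row(code, group, subgroup, ingredients, **kw):
    row = {c: 0.0 for c in FOOD_COLUMNS}
    row.update(
        food_code=code,
        description=code,
        foodex2_group=group,
        foodex2_subgroup=subgroup,
        ingredients_text=ingredients,
        nova_class=1,
    )
    row.update(kw)
    row["energy_kj"] = round(row["energy_kcal"] * 4.184, 2)
    return row


@pytest.fixture(scope="session")
def hand_foods() -> pd.DataFrame:
    """Five foods with fully known species sets and nutrients."""
    rows = [
        _food_row(
            "F1", "grains_grain_products", "bread", "Wheat Flour (60%), Salt",
            energy_kcal=250.0, protein_g=9.0, fibre_g=4.0, sodium_mg=400.0,
            saturated_fat_g=0.5, nova_class=3, ghg_per_kg=800.0, price_per_100g=0.15,
        ),
        _food_row(
            "F2", "composite_dishes", "pasta_dishes",
            "Durum Wheat, Tomatoes (60%), Basil",
            energy_kcal=150.0, protein_g=5.0, fibre_g=2.5, free_sugars_g=1.0,
            fv_g_per_100g=40.0, nova_class=3, ghg_per_kg=1900.0, price_per_100g=0.55,
        ),
        _food_row(
            "F3", "composite_dishes", "meat_dishes",
            "Beef (20%), Tomato Purée, Wheat flour, Milk, Cheese",
            energy_kcal=180.0, protein_g=10.0, saturated_fat_g=4.0,
            red_meat_g_per_100g=20.0, sodium_mg=350.0, nova_class=4,
            ghg_per_kg=5200.0, price_per_100g=0.80,
        ),
        _food_row(
            "F4", "fruit_fruit_products", "fresh_fruit", "Apples",
            energy_kcal=52.0, free_sugars_g=0.0, fibre_g=2.4, fv_g_per_100g=100.0,
            vitamin_c_mg=5.0, nova_class=1, ghg_per_kg=400.0, price_per_100g=0.22,
        ),
        _food_row("F5", "beverages", "water", "Water", energy_kcal=0.0, nova_class=1,
                  ghg_per_kg=30.0, price_per_100g=0.05),
    ]
    return pd.DataFrame(rows)


#: hand-computed species sets for hand_foods under toy_dict
HAND_SPECIES = {
    "F1": {"wheat"},
    "F2": {"wheat", "tomato", "basil"},
    "F3": {"cattle", "tomato", "wheat"},
    "F4": {"apple"},
    "F5": set(),
}


@pytest.fixture(scope="session")
def hand_diaries() -> pd.DataFrame:
    rows = [
        # P1: four days
        ("P1", 1, "F1", 100.0), ("P1", 1, "F2", 200.0),
        ("P1", 2, "F3", 300.0),
        ("P1", 3, "F4", 150.0),
        ("P1", 4, "F5", 500.0),
        # P2: three days, same food daily
        ("P2", 1, "F4", 120.0), ("P2", 2, "F4", 120.0), ("P2", 3, "F4", 120.0),
        # P3: two days only -> excluded by the completer rule
        ("P3", 1, "F1", 80.0), ("P3", 2, "F2", 90.0),
    ]
    return pd.DataFrame(rows, columns=["participant_id", "day", "food_code", "grams"])


@pytest.fixture(scope="session")
def hand_participants() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": ["P1", "P2", "P3"],
            "age_group": ["adults", "children", "elders"],
            "sex": ["female", "male", "female"],
            "ethnicity": ["white", "asian", "white"],
            "bmi_category": ["normal", "overweight", "normal"],
            "imd_quintile": [1, 3, 5],
            "income_tertile": [1, 2, 3],
            "marital_status": ["single", "married", "widow"],
        }
    )
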