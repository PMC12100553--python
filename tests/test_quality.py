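"""NRF8.3 scoring, intake summaries and guideline adherence."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dsr.foods import NutrientProfile
from dsr.quality import (
    GUIDELINE_CUTOFFS,
    HIGH_PROCESSED_CUTOFF,
    AdherenceProfile,
    IntakeSummary,
    ReferenceValues,
    classify_adherence,
    intake_summary,
    load_reference_values,
    nrf83_score,
    participant_mean_nrf,
)


@pytest.fixture(scope="module")
def rv() -> ReferenceValues:
    return load_reference_values()


def profile(energy=100.0, **kw):
    return NutrientProfile(energy_kcal=energy, energy_kj=energy * 4.184, **kw)


class TestNRF83:
    def test_all_zero_nutrients_scores_zero(self, rv):
        assert nrf83_score(profile(), rv) == 0.0

    def test_each_qualifying_at_dv_scores_800(self, rv):
        # per 100 kcal basis with energy 100 kcal/100 g: amounts equal DVs
        amounts = {k: v for k, v in rv.qualifying.items()}
        assert nrf83_score(profile(**amounts), rv) == pytest.approx(800.0)

    def test_qualifying_capped_at_100(self, rv):
        dv = rv.qualifying["protein_g"]
        capped = nrf83_score(profile(protein_g=2 * dv), rv)
        at_dv = nrf83_score(profile(protein_g=dv), rv)
        assert capped == pytest.approx(at_dv) == pytest.approx(100.0)

    def test_limiting_uncapped(self, rv):
        mrv = rv.limiting["saturated_fat_g"]
        assert nrf83_score(profile(saturated_fat_g=2 * mrv), rv) == pytest.approx(-200.0)

    def test_zero_energy_raises(self, rv):
        with pytest.raises(ValueError, match="zero-energy"):
            nrf83_score(profile(energy=0.0), rv)

    def test_mass_basis_invariance(self, rv):
        # same food expressed per 100 g and per 50 g serving: identical score
        per_100g = profile(energy=200.0, protein_g=10.0, fibre_g=4.0, sodium_mg=300.0)
        per_50g = profile(energy=100.0, protein_g=5.0, fibre_g=2.0, sodium_mg=150.0)
        assert nrf83_score(per_100g, rv) == pytest.approx(nrf83_score(per_50g, rv))


def _quality_foods():
    rows = []
    for code, energy, protein in [("A", 100.0, 0.0), ("B", 100.0, 0.0)]:
        rows.append(
            {
                "food_code": code,
                "energy_kcal": energy,
                "energy_kj": energy * 4.184,
                "protein_g": protein,
                "fibre_g": 0.0,
                "vitamin_a_ug": 0.0,
                "vitamin_c_mg": 0.0,
                "vitamin_e_mg": 0.0,
                "calcium_mg": 0.0,
                "iron_mg": 0.0,
                "potassium_mg": 0.0,
                "magnesium_mg": 0.0,
                "saturated_fat_g": 0.0,
                "free_sugars_g": 0.0,
                "sodium_mg": 0.0,
            }
        )
    foods = pd.DataFrame(rows)
    # food A scores 100 (protein at DV per 100 kcal), food B scores 300
    foods.loc[foods["food_code"] == "A", "protein_g"] = 50.0
    foods.loc[foods["food_code"] == "B", "protein_g"] = 50.0
    foods.loc[foods["food_code"] == "B", ["fibre_g", "vitamin_c_mg"]] = [28.0, 90.0]
    return foods


class TestParticipantNRF:
    def test_single_food_diet_equals_food_score(self, rv):
        foods = _quality_foods()
        diary = pd.DataFrame(
            [("P", 1, "A", 100.0)], columns=["participant_id", "day", "food_code", "grams"]
        )
        assert participant_mean_nrf(diary, foods, rv) == pytest.approx(100.0)

    def test_equal_energy_foods_average(self, rv):
        foods = _quality_foods()
        diary = pd.DataFrame(
            [("P", 1, "A", 100.0), ("P", 1, "B", 100.0)],
            columns=["participant_id", "day", "food_code", "grams"],
        )
        assert participant_mean_nrf(diary, foods, rv) == pytest.approx(200.0)

    def test_doubling_grams_leaves_weighted_mean_unchanged(self, rv):
        foods = _quality_foods()
        diary = pd.DataFrame(
            [("P", 1, "A", 100.0), ("P", 1, "B", 60.0)],
            columns=["participant_id", "day", "food_code", "grams"],
        )
        doubled = diary.assign(grams=diary["grams"] * 2)
        assert participant_mean_nrf(diary, foods, rv) == pytest.approx(
            participant_mean_nrf(doubled, foods, rv)
        )

    def test_unweighted_mode(self, rv):
        foods = _quality_foods()
        diary = pd.DataFrame(
            [("P", 1, "A", 300.0), ("P", 1, "B", 100.0)],
            columns=["participant_id", "day", "food_code", "grams"],
        )
        unweighted = participant_mean_nrf(diary, foods, rv, weighted=False)
        weighted = participant_mean_nrf(diary, foods, rv, weighted=True)
        assert unweighted == pytest.approx(200.0)
        assert weighted == pytest.approx((300 * 100 + 100 * 300) / 400)


def _intake_foods(**overrides):
    row = {
        "food_code": "X",
        "energy_kcal": 100.0,
        "saturated_fat_g": 0.0,
        "free_sugars_g": 0.0,
        "sodium_mg": 0.0,
        "fibre_g": 0.0,
        "red_meat_g_per_100g": 0.0,
        "fish_g_per_100g": 0.0,
        "fv_g_per_100g": 0.0,
        "nova_class": 1,
    }
    row.update(overrides)
    return pd.DataFrame([row])


def _one_day_diary(grams):
    return pd.DataFrame(
        [("P", 1, "X", grams)], columns=["participant_id", "day", "food_code", "grams"]
    )


class TestIntakeSummary:
    def test_sfa_energy_percent_uses_9_kcal_per_g(self):
        # 2000 kcal with 24.4 g SFA -> 24.4*9/2000 = 10.98 %
        foods = _intake_foods(energy_kcal=100.0, saturated_fat_g=1.22)
        s = intake_summary(_one_day_diary(2000.0), foods)
        assert s.sfa_energy_pct == pytest.approx(10.98)

    def test_salt_from_sodium_conversion(self):
        foods = _intake_foods(sodium_mg=120.0)
        s = intake_summary(_one_day_diary(2000.0), foods)
        assert s.salt_g_per_day == pytest.approx(6.0)

    def test_fish_weekly_equivalent(self):
        foods = _intake_foods(fish_g_per_100g=40.0)
        diary = pd.DataFrame(
            [("P", d, "X", 100.0) for d in range(1, 5)],
            columns=["participant_id", "day", "food_code", "grams"],
        )
        s = intake_summary(diary, foods)
        assert s.fish_g_per_week == pytest.approx(280.0)

    def test_upf_energy_share_from_nova_3_and_4(self):
        foods = pd.concat(
            [
                _intake_foods(nova_class=1),
                _intake_foods(nova_class=4).assign(food_code="Y"),
            ]
        )
        diary = pd.DataFrame(
            [("P", 1, "X", 100.0), ("P", 1, "Y", 300.0)],
            columns=["participant_id", "day", "food_code", "grams"],
        )
        s = intake_summary(diary, foods)
        assert s.upf_energy_pct == pytest.approx(75.0)

    def test_unknown_food_code_raises(self):
        with pytest.raises(KeyError, match="unknown food codes"):
            intake_summary(_one_day_diary(100.0).assign(food_code="Z"), _intake_foods())


def random_summary(rng) -> IntakeSummary:
    return IntakeSummary(
        participant_id="P",
        energy_kcal_per_day=float(rng.uniform(800, 3500)),
        sfa_energy_pct=float(rng.uniform(0, 25)),
        free_sugars_energy_pct=float(rng.uniform(0, 20)),
        red_meat_g_per_day=float(rng.uniform(0, 150)),
        salt_g_per_day=float(rng.uniform(0, 15)),
        fibre_g_per_day=float(rng.uniform(0, 60)),
        fv_g_per_day=float(rng.uniform(0, 900)),
        fish_g_per_week=float(rng.uniform(0, 700)),
        upf_energy_pct=float(rng.uniform(0, 100)),
    )


class TestAdherence:
    @pytest.mark.parametrize(
        "field, value, expected",
        [
            ("fibre_g_per_day", 31.0, True),
            ("fibre_g_per_day", 30.0, False),   # strict "more than"
            ("sfa_energy_pct", 11.0, False),    # strict "less than"
            ("sfa_energy_pct", 10.99, True),
            ("fv_g_per_day", 400.0, False),
            ("fish_g_per_week", 280.0, False),
            ("salt_g_per_day", 6.0, False),
            ("red_meat_g_per_day", 69.99, True),
            ("free_sugars_energy_pct", 5.0, False),
        ],
    )
    def test_boundary_cases_strict_as_printed(self, field, value, expected):
        base = dict(
            participant_id="P",
            energy_kcal_per_day=2000.0,
            sfa_energy_pct=5.0,
            free_sugars_energy_pct=2.0,
            red_meat_g_per_day=10.0,
            salt_g_per_day=3.0,
            fibre_g_per_day=35.0,
            fv_g_per_day=500.0,
            fish_g_per_week=300.0,
            upf_energy_pct=30.0,
        )
        base[field] = value
        prof = classify_adherence(IntakeSummary(**base))
        flag = {
            "fibre_g_per_day": "fibre_ok",
            "sfa_energy_pct": "sfa_ok",
            "fv_g_per_day": "fv_ok",
            "fish_g_per_week": "fish_ok",
            "salt_g_per_day": "salt_ok",
            "red_meat_g_per_day": "red_meat_ok",
            "free_sugars_energy_pct": "free_sugars_ok",
        }[field]
        assert getattr(prof, flag) is expected

    def test_exactly_60_percent_upf_is_high_processed(self):
        s = random_summary(np.random.default_rng(0))
        s = IntakeSummary(**{**s.__dict__, "upf_energy_pct": 60.0})
        assert classify_adherence(s).high_processed_eater is True

    def test_agrees_with_brute_force_on_1000_random_summaries(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            s = random_summary(rng)
            prof = classify_adherence(s)
            # independent threshold check, written from the cut-off table
            expected = {
                "sfa_ok": s.sfa_energy_pct < 11.0,
                "free_sugars_ok": s.free_sugars_energy_pct < 5.0,
                "red_meat_ok": s.red_meat_g_per_day < 70.0,
                "salt_ok": s.salt_g_per_day < 6.0,
                "fibre_ok": s.fibre_g_per_day > 30.0,
                "fv_ok": s.fv_g_per_day > 400.0,
                "fish_ok": s.fish_g_per_week > 280.0,
                "high_processed_eater": s.upf_energy_pct >= 60.0,
            }
            for flag, want in expected.items():
                assert getattr(prof, flag) == want
            assert prof.all_ok == all(
                v for k, v in expected.items() if k != "high_processed_eater"
            )

    def test_all_ok_conjunction_enforced(self):
        with pytest.raises(ValueError, match="conjunction"):
            AdherenceProfile(
                participant_id="P",
                sfa_ok=True,
                free_sugars_ok=True,
                red_meat_ok=True,
                salt_ok=True,
                fibre_ok=True,
                fv_ok=True,
                fish_ok=False,
                all_ok=True,
                high_processed_eater=False,
            )


def test_reference_values_must_be_positive():
    with pytest.raises(ValueError):
        ReferenceValues(qualifying={"protein_g": 0.0}, limiting={"sodium_mg": 2300.0})


def test_cutoff_table_matches_guideline_text():
    # seven guidelines, comparison direction as printed
    assert GUIDELINE_CUTOFFS["fibre_g_per_day"] == (">", 30.0)
    assert GUIDELINE_CUTOFFS["sfa_energy_pct"] == ("<", 11.0)
    assert len(GUIDELINE_CUTOFFS) == 7 and HIGH_PROCESSED_CUTOFF == 60.0
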