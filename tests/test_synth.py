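"""Synthetic-data generators: determinism, structure, mechanism checks."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from dsr.foods import annotate_food_table
from dsr.species import match_species
from dsr.synth import (
    GeneratorConfig,
    calibrate,
    generate_cohort,
    generate_food_database,
    generate_species_pool,
    simulate_accumulation_medians,
)

SMALL = GeneratorConfig(seed=3, n_species=60, n_foods=400, n_participants=50)


@pytest.fixture(scope="module")
def small_world():
    dictionary = generate_species_pool(SMALL)
    foods = generate_food_database(SMALL, dictionary)
    diaries, participants = generate_cohort(SMALL, foods)
    return dictionary, foods, diaries, participants


class TestDeterminism:
    def test_species_pool_reproducible(self):
        a = generate_species_pool(SMALL)
        b = generate_species_pool(SMALL)
        assert [r == s for r, s in zip(a.records, b.records)]
        assert a.index == b.index

    def test_food_database_reproducible(self):
        d = generate_species_pool(SMALL)
        a = generate_food_database(SMALL, d)
        b = generate_food_database(SMALL, d)
        pd.testing.assert_frame_equal(a, b)

    def test_cohort_reproducible(self, small_world):
        _, foods, diaries, participants = small_world
        diaries2, participants2 = generate_cohort(SMALL, foods)
        pd.testing.assert_frame_equal(diaries, diaries2)
        pd.testing.assert_frame_equal(participants, participants2)

    def test_different_seed_differs(self, small_world):
        _, foods, diaries, _ = small_world
        other, _ = generate_cohort(replace(SMALL, seed=4), foods)
        assert not diaries.equals(other)


class TestSpeciesPool:
    def test_requested_size_and_unique_ids(self):
        d = generate_species_pool(GeneratorConfig(seed=0, n_species=216))
        assert len(d) == 216
        assert len(set(d.species_ids)) == 216

    def test_category_proportions_near_config(self):
        cfg = GeneratorConfig(seed=1, n_species=216)
        d = generate_species_pool(cfg)
        counts = pd.Series([r.category for r in d.records]).value_counts(normalize=True)
        for cat, want in cfg.category_proportions.items():
            assert counts.get(cat, 0.0) == pytest.approx(want, abs=0.02), cat

    def test_every_record_has_synonyms(self):
        d = generate_species_pool(SMALL)
        assert all(1 <= len(r.common_names) <= 4 for r in d.records)


class TestFoodDatabase:
    def test_round_trip_matcher_recovers_recipes(self, small_world):
        dictionary, foods, _, _ = small_world
        for text, expected in zip(foods["ingredients_text"], foods["species_set"]):
            assert match_species(text, dictionary) == expected

    def test_annotation_matches_generator_truth(self, small_world):
        dictionary, foods, _, _ = small_world
        ann = annotate_food_table(
            foods.drop(columns=["species_set", "dsr"]), dictionary, warn_empty=False
        )
        assert list(ann["species_set"]) == list(foods["species_set"])

    def test_group_medians_hit_targets_at_scale(self):
        cfg = GeneratorConfig(seed=2)
        d = generate_species_pool(cfg)
        foods = generate_food_database(cfg, d)
        med = foods.groupby("foodex2_group")["dsr"].median()
        targets = {
            "composite_dishes": 8,
            "seasoning_sauces_condiments": 7,
            "grains_grain_products": 5,
            "meat_dairy_substitutes": 4,
            "confectionery": 4,
        }
        for grp, want in targets.items():
            assert abs(med[grp] - want) <= 1, grp
        others = med.drop(index=list(targets))
        assert (others <= 2.5).all()

    def test_nrf_dsr_slope_induces_quality_gradient(self):
        from scipy.stats import spearmanr

        from dsr.quality import food_table_nrf, load_reference_values

        rv = load_reference_values()
        cfg = replace(SMALL, n_foods=800, nrf_dsr_slope=0.2)
        d = generate_species_pool(cfg)
        foods = generate_food_database(cfg, d)
        ok = foods["energy_kcal"] > 0
        rho, _ = spearmanr(foods.loc[ok, "dsr"], food_table_nrf(foods[ok], rv))
        flat = generate_food_database(replace(cfg, nrf_dsr_slope=0.0), d)
        rho0, _ = spearmanr(flat.loc[ok, "dsr"], food_table_nrf(flat[ok], rv))
        assert rho > rho0 + 0.1
        assert rho > 0.2

    def test_nova_and_popularity_columns_valid(self, small_world):
        _, foods, _, _ = small_world
        assert foods["nova_class"].isin([1, 2, 3, 4]).all()
        assert sorted(foods["popularity_rank"]) == list(range(1, len(foods) + 1))


class TestCohort:
    def test_diary_codes_all_exist(self, small_world):
        _, foods, diaries, _ = small_world
        assert set(diaries["food_code"]) <= set(foods["food_code"])

    def test_every_participant_has_3_or_4_days(self, small_world):
        _, _, diaries, participants = small_world
        days = diaries.groupby("participant_id")["day"].nunique()
        assert days.isin([3, 4]).all()
        assert len(days) == len(participants)

    def test_full_repeat_propensity_freezes_menu(self):
        cfg = replace(SMALL, repeat_propensity=1.0, p_three_day=0.0)
        d = generate_species_pool(cfg)
        foods = generate_food_database(cfg, d)
        diaries, _ = generate_cohort(cfg, foods)
        for _, sub in diaries.groupby("participant_id"):
            day1 = set(sub.loc[sub["day"] == 1, "food_code"])
            for day in (2, 3, 4):
                assert set(sub.loc[sub["day"] == day, "food_code"]) <= day1

    def test_uniform_sampling_matches_coupon_collector_expectation(self):
        """With no repeat draws and a uniform popularity over a repertoire
        equal to the whole (small) food set, the expected cumulative
        distinct-species count after n draws has the closed form
        sum_s 1 - (1 - q_s)^n with q_s the fraction of foods containing s."""
        cfg = GeneratorConfig(
            seed=9,
            n_species=40,
            n_foods=30,
            n_participants=400,
            repeat_propensity=0.0,
            food_popularity_exponent=0.0,
            within_repertoire_exponent=0.0,
            repertoire_size=30,
            preference_breadth=50.0,  # effectively no personal tilt
            foods_per_day_mean=10.0,
            foods_per_day_sd=0.0,
            p_three_day=0.0,
            age_effects={"children": 1, "adolescents": 1, "adults": 1, "elders": 1},
            income_effects={1: 1, 2: 1, 3: 1},
            imd_effect_per_quintile=0.0,
        )
        d = generate_species_pool(cfg)
        foods = generate_food_database(cfg, d)
        diaries, _ = generate_cohort(cfg, foods)
        sets = dict(zip(foods["food_code"], foods["species_set"]))
        all_species = set().union(*sets.values())
        q = {
            s: sum(s in v for v in sets.values()) / len(sets) for s in all_species
        }
        cum_by_day = {1: [], 2: [], 3: [], 4: []}
        for _, sub in diaries.groupby("participant_id"):
            seen = set()
            for day in (1, 2, 3, 4):
                for c in sub.loc[sub["day"] == day, "food_code"]:
                    seen |= sets[c]
                cum_by_day[day].append(len(seen))
        for day in (1, 2, 3, 4):
            n_draws = 10 * day
            expected = sum(1 - (1 - qs) ** n_draws for qs in q.values())
            observed = np.mean(cum_by_day[day])
            se = np.std(cum_by_day[day]) / np.sqrt(len(cum_by_day[day]))
            assert abs(observed - expected) < max(4 * se, 0.5), day

    def test_repeat_propensity_monotone_in_day2_increment(self):
        cfg = replace(SMALL, n_participants=200, p_three_day=0.0)
        d = generate_species_pool(cfg)
        foods = generate_food_database(cfg, d)
        day2 = []
        for r in (0.1, 0.5, 0.9):
            _, m2, _, _ = simulate_accumulation_medians(
                replace(cfg, repeat_propensity=r), foods, 200, seed=77
            )
            day2.append(m2)
        assert day2[0] >= day2[1] >= day2[2]

    def test_demographic_gradient_direction(self):
        cfg = GeneratorConfig(seed=6, n_foods=2000, n_participants=600, p_three_day=0.0)
        d = generate_species_pool(cfg)
        foods = generate_food_database(cfg, d)
        diaries, participants = generate_cohort(cfg, foods)
        sets = dict(zip(foods["food_code"], foods["species_set"]))
        totals = {}
        for pid, sub in diaries.groupby("participant_id"):
            seen = set()
            for c in sub["food_code"]:
                seen |= sets[c]
            totals[pid] = len(seen)
        frame = participants.assign(
            total=lambda p: p["participant_id"].map(totals)
        )
        by_income = frame.groupby("income_tertile")["total"].mean()
        assert by_income[3] > by_income[1]


class TestCalibration:
    def test_fixed_point_converges_immediately(self):
        cfg = GeneratorConfig(seed=8, n_foods=1500, n_participants=300)
        d = generate_species_pool(cfg)
        foods = generate_food_database(cfg, d)
        eval_seed = (cfg.seed * 7919 + 17) % (2**31 - 1)
        m1, m2, _, _ = simulate_accumulation_medians(cfg, foods, 400, eval_seed)
        calibrated, report = calibrate(
            cfg, target_day1_median=m1, target_day2_increment=m2, n_eval=400
        )
        assert report.converged
        assert report.iterations <= 2
        assert calibrated.food_popularity_exponent == cfg.food_popularity_exponent
        assert calibrated.repeat_propensity == cfg.repeat_propensity

    def test_nonconvergence_reported_not_raised(self):
        cfg = GeneratorConfig(seed=8, n_foods=800, n_participants=200)
        _, report = calibrate(
            cfg, target_day1_median=500.0, target_day2_increment=9.0, n_eval=150
        )
        assert report.converged is False
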