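# dsr — dietary species richness analysis

Tools for measuring **food biodiversity in diet-survey data**. Dietary
species richness (DSR) is the number of distinct biological species a
person consumes over a stated period, counted across all foods and
drinks — including every ingredient of composite dishes. It has been
proposed as a simple, comprehensive metric linking diet quality with
agricultural and wild biodiversity, and it can be computed from the
4-day estimated food diaries used by the UK National Diet and Nutrition
Survey (NDNS) once the nutrient databank is annotated with ingredient
lists.

The package implements the full analysis chain for epidemiologists and
nutrition researchers working with NDNS-style data:

* **Species dictionary** (`dsr.species`) — species records with
  synonyms, a compiled normalized-synonym index, and deterministic
  longest-match-first, word-boundary matching of species to free-text
  ingredient lists ("pineapple juice" never matches *apple*;
  flavourings in coded nomenclature never match at all). Manual
  curation is replaced by a machine-readable override file.
* **Food database** (`dsr.foods`) — per-food DSR annotation,
  FoodEx2-style group summaries (median, Q1, Q3), and Spearman
  correlations of DSR with energy density, greenhouse-gas emissions and
  price, Bonferroni-adjusted.
* **Diary pipeline** (`dsr.diary`) — the 3-or-4-day completer rule,
  per-day new-species counts, the cumulative species accumulation
  curve, cohort summaries, and the 2-day coverage statistic
  (median 2-day cumulative DSR ÷ median 4-day cumulative DSR).
* **Diet quality** (`dsr.quality`) — the Nutrient Rich Food index
  NRF8.3 per 418 kJ (100 kcal),

  NRF8.3 = Σ₈ min(100, 100·amountᵢ/DVᵢ) − Σ₃ 100·amountⱼ/MRVⱼ,

  with amounts per 100 kcal, eight qualifying nutrients capped at their
  daily value and three limiting nutrients (saturated fat, free sugars,
  sodium) uncapped; participant scores are energy-weighted means.
  Guideline adherence uses the UK cut-offs with strict comparisons
  (SFA < 11 %E, free sugars < 5 %E, red meat < 70 g/d, salt < 6 g/d,
  fibre > 30 g/d, fruit & veg > 400 g/d, fish > 280 g/wk) plus the
  ≥ 60 %-processed-energy "high processed food eater" flag.
* **Statistics** (`dsr.stats`) — Spearman with Fisher-z CIs and explicit
  Bonferroni family sizes, tie-corrected Kruskal–Wallis, OLS with
  declared dummy reference levels and tolerance-based collinearity
  screening.
* **Synthetic cohort** (`dsr.synth`) — the NDNS databank and diaries are
  access-restricted, so the package generates statistically faithful
  stand-ins: a 216-species pool, a 6,000-item food database whose
  ingredient texts encode known recipes, and a 3,558-participant 4-day
  diary cohort driven by a two-parameter consumption mechanism (Zipf
  food popularity + personal repertoires with repeat draws) that is
  *calibrated* against exactly two statistics — the day-1 median DSR
  (29) and the day-2 median increment (9). All later-day statistics are
  out-of-sample predictions of the fitted mechanism.

A curated 269-species reference list (real edible species with real
synonyms; a synthetic stand-in for the restricted supplementary list)
ships with the package.

## Worked example

Run the numbered analysis scripts from the repository root (synthetic
inputs are written to `scratch/synthetic/`, result tables to
`results/`):

```
$ python analysis/01_generate_cohort.py 1
calibration converged=True in 2 evaluations: popularity exponent 0.600, repeat propensity 0.450
generated 216 species, 6000 foods, 3558 participants, 209290 consumptions -> scratch/synthetic

$ python analysis/02_food_level_dsr.py
food-group DSR medians (top 5):
              foodex2_group   n  median_dsr  q1    q3
           composite_dishes 743         8.0 5.0 11.00
seasoning_sauces_condiments 335         7.0 5.0 10.00
      grains_grain_products 862         5.0 3.0  7.00
              confectionery 444         4.0 3.0  6.00
     meat_dairy_substitutes 188         4.0 3.0  5.25

$ python analysis/03_species_accumulation.py
  day    n  new_median  ...  cumulative_median
    1 3558        29.0  ...               29.0
    2 3558         9.0  ...               39.0
    3 3558         6.0  ...               47.0
    4 3267         4.0  ...               53.0
total 3558         NaN  ...               52.0
two-day coverage of the 4-day median DSR: 73.6%
```

Composite dishes carry the most species per item (median 8), followed
by seasonings and sauces (7) and grain products (5). At the diet level
the median participant accumulates 29 species on day 1, 9 more on day
2, then 6 and 4 — about three quarters of the 4-day richness is seen in
the first two diary days. `analysis/04_diet_quality.py` and
`analysis/05_statistics.py` continue with adherence rates, Kruskal–
Wallis tests (DSR differs by age, income and deprivation, not by sex,
ethnicity or BMI in the synthetic cohort) and the regression tables.

The same chain is available as a CLI (`dsr generate`, `dsr annotate`,
`dsr dsr`, `dsr quality`, `dsr run-all`) for use on real input tables;
`dsr run-all --config pipeline.yaml` writes every output plus a
manifest, and re-running a configuration reproduces byte-identical
files.

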