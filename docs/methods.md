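# Methods

## Dietary species richness

DSR counts distinct biological species, not foods: a lasagne
contributes wheat, cattle (beef, milk and cheese are one species),
tomato, onion and every herb its ingredient list names. Food-level DSR
is the size of the species set matched from the ingredient text;
diet-level DSR is the union of those sets over everything a participant
consumed, so gram amounts never enter the calculation and a species
eaten twice counts once. The day-wise accumulation curve reports, per
diary day, the count of species not seen on earlier days; its running
sum is the cumulative DSR and the day-4 value is the participant's
4-day DSR.

## Ingredient matching

Matching is exact, deterministic and token-based. Normalization
lower-cases, folds diacritics (purée → puree), strips punctuation and
numeric/percentage annotations, and removes only *regular* English
plural suffixes (-s, -es, -ies → -y); irregular plurals must be listed
as explicit synonyms. The transform is idempotent. A synonym matches
only as a contiguous whole-token subsequence; longer synonyms are tried
first and consume their tokens, so a nested shorter synonym of another
species cannot double-match ("pineapple" blocks "apple" because the
match operates on whole tokens in any case). Exclusion terms
("flavouring", "extract", …) never match and never consume tokens:
"vanilla extract" still credits vanilla, while "flavouring (E471)" —
a coded nomenclature with no species token — matches nothing.
Curation decisions that a human reviewer would make are expressed as a
machine-readable override file (pattern → force-include/exclude
species) applied after automatic matching, keeping runs reproducible.

Equivalence with a brute-force regex word-boundary oracle holds on any
dictionary in which no species' synonym is a token-subsequence of
another species' synonym; the packaged and generated dictionaries
satisfy this, and the property suite checks the equivalence on
randomized fixtures.

## The packaged species list

The reference list used to annotate a real nutrient databank is not
redistributable, so the package ships a curated stand-in
(`species_dictionary_synthetic_269.csv`): 269 real edible species with
real synonym sets, built to the published list's size and approximate
category mix (fish and aquatic species the largest share, then fruits
and vegetables). Botanical identity is respected — cabbage, broccoli,
cauliflower, kale and Brussels sprouts are all *Brassica oleracea*;
peach and nectarine are one species — which is exactly what makes
species richness differ from food-variety counts.

## NRF8.3 per 100 kcal

Scores are computed per 418 kJ (100 kcal): amount-per-100 kcal =
amount-per-100 g × 100 / energy-kcal-per-100 g. Eight qualifying
nutrients contribute min(100, 100 · amount/DV); three limiting
nutrients (saturated fat, free sugars, sodium) subtract
100 · amount/MRV uncapped. The qualifying set and every DV/MRV value
live in a YAML table, not in code; the shipped defaults (protein 50 g,
fibre 28 g, vitamin A 900 µg, vitamin C 90 mg, vitamin E 15 mg,
calcium 1300 mg, iron 18 mg, potassium 4700 mg; limits 20 g / 50 g /
2300 mg) follow widely used nutrient-profiling daily values, with
magnesium available as a configurable swap. Zero-energy foods have no
per-100 kcal basis and raise an error; at the participant level they
carry zero energy weight and are skipped. Participant scores are
energy-weighted means of food scores by default (unweighted mode is a
switch), making the score invariant to scaling all portions.

Intake summaries use 9 kcal/g for saturated-fat energy, 4 kcal/g for
free sugars (3.75 kcal/g UK convention available), salt = sodium ×
2.5/1000, fish weekly equivalent = mean daily grams × 7, and the
processed-energy share sums energy from NOVA classes 3–4. Guideline
comparisons are strict exactly as the guidelines print them (`<`, `>`,
and `≥ 60 %` for the high-processed flag), so boundary values such as
exactly 30 g fibre/day do not qualify. Red-meat, fish and
fruit-and-veg gram contributions are database columns per 100 g of
food, because decomposing composite dishes is a property of the food
table, not of the diary arithmetic.

## Statistics

Spearman correlations use midrank ties with Fisher-z 95 % intervals;
Bonferroni family sizes are always explicit at the call site (adjusted
p = min(1, m·p)). Kruskal–Wallis uses the tie-corrected H statistic
with a χ² reference on k−1 degrees of freedom; an all-identical sample
is defined as H = 0, p = 1. Regressions are ordinary least squares with
categorical predictors dummy-coded against declared reference levels
(youngest age group, lowest income tertile, most deprived quintile,
non-adherent); per-predictor tolerance (1 − R² of that predictor on the
others) below 0.1 logs a collinearity warning. Shapiro–Wilk is provided
as a reporting wrapper only. Quantiles everywhere use linear
interpolation (R type 7), a fixed package-wide convention.

## The synthetic cohort generator

The generator's job is to reproduce the statistical structure a
4-day national diet survey exhibits, so the pipeline can be exercised
and its cohort statistics compared with published values without the
restricted data.

**Species pool.** 216 species (the number found in the real databank's
foods) with fabricated unique names, 1–4 synonyms each, and
configurable category proportions (defaults 0.29 fish/aquatic, 0.24
fruit, 0.22 vegetable, remainder spread).

**Food database.** 6,000 foods across 13 FoodEx2-style groups. Recipe
sizes are rounded lognormals with per-group medians chosen to match the
observed food-level DSR pattern (composite dishes 8, seasonings 7,
grains 5, substitutes and confectionery 4, remaining groups 1–2);
recipes draw species without replacement, weighted by a fixed
species-popularity law (exponent 0.7, chosen so common species recur
across recipes while cohort day-1 richness remains reachable) times an
8× category-affinity boost per group. Ingredient
text renders each recipe from randomly chosen synonyms with occasional
percentage annotations, so annotation must recover the recipe exactly
(a tested round trip). Nutrients, GHG and price come from group-level
lognormals; GHG and price rise mildly with recipe size, giving the
positive food-level correlations observed in practice. Food
*popularity* is a fixed column of the database: a seeded ranking in
which low-DSR staples (plain breads, milk, tea) dominate the top and
composite dishes sit lower, which is what makes the popularity exponent
an effective lever on cohort day-1 richness.

**Consumption mechanism.** Each participant draws a personal
repertoire — the ~40 foods they rotate during the diary window —
without replacement from popularity^exponent tilted by gamma noise
(shape 0.6 × a demographic multiplier), then consumes uniformly within
it: ~15 foods/day (normal, sd 2; sub-Poisson because meals are fixed
slots). Day 1 is all fresh draws; on later days each consumption is,
with probability `repeat_propensity`, a uniform redraw from foods
already eaten. Demographic gradients (age, income tertile, deprivation
quintile) scale the foods-per-day mean, repertoire size and preference
breadth by a few percent, producing the higher-DSR-in-younger/richer/
less-deprived pattern without touching the species dictionary. A
configured fraction (8 %) completes only three days, exercising the
completer rule. An optional `nrf_dsr_slope` makes species-richer
recipes more nutrient-dense for regression-recovery tests; it defaults
to 0, so the default cohort carries no built-in diet-quality gradient.

**Calibration.** Exactly two statistics are fitted: the day-1 median
distinct-species count (target 29) and the day-2 median increment
(target 9). Because day 1 involves no repeat draws, the day-1 median
depends on the popularity exponent alone; it is bisected first (range
0–1.8), then the repeat propensity is bisected against the day-2
increment (range 0.02–0.98). Every evaluation simulates 1,000
participants under a fixed evaluation seed (spec floor: 500); bisection
aims at ±0.5 species so that a fresh full-size cohort stays within the
±1-species convergence tolerance. If the current parameters already
reproduce the targets, calibration is a two-evaluation no-op.
Day-3/day-4 increments, the 4-day total and the 2-day coverage are
never consulted — they are out-of-sample predictions of the fitted
mechanism.

**What the defaults predict.** Across seeds 0–5 the calibrated cohorts
give day-3 median increment 6, day-4 increment 4–5, 4-day median DSR
51–53 and 2-day coverage 73–76 % (observed values: 5, 4, 49, 80 %).
The day-3/day-4 shape is reproduced; the 4-day total runs 2–4 species
high because the invented mechanism carries somewhat stronger
cross-day, per-person dependence than the real cohort — the median of
4-day totals exceeds the sum of daily increment medians by ~4, versus
~2 in the survey — which also depresses the coverage ratio by a few
points. These residuals are reported as-is; no constant was adjusted
against the held-out statistics after the mechanism was frozen.

**What passing tests do and do not show.** The generator emulates menu
repetition, popularity concentration, recipe structure and demographic
consumption gradients. It does not emulate real food codes, survey
weights, portion-size distributions, seasonality, weekday/weekend
structure, under-reporting, or correlations between demographics and
marital status (the synthetic cohort shows no marital-status effect).
Agreement on the synthetic cohort therefore validates the pipeline's
arithmetic and the plausibility of the accumulation mechanism, not any
claim about the real survey population.

## Numerical and degenerate-input conventions

Seeds propagate through `numpy.random.SeedSequence` children per
generator stage, so every artifact is reproducible from one integer.
Species sets serialize as sorted semicolon-joined ids; pipeline re-runs
are byte-identical, and the run manifest records the configuration hash
(excluding the output directory) rather than timestamps. Empty
ingredient text yields an empty species set with a logged warning
(water and salt legitimately match nothing); an unknown diary food code
aborts with every missing code named; a diary day with no consumptions
does not count towards the 3-day completer rule. Statistical steps that
a tiny cohort cannot support (a constant stratum, n ≤ number of
coefficients) are skipped with a logged note rather than failing the
whole run.

## Analysis problem sizes

The shipped analysis scripts and acceptance run use the full study
dimensions (216 species, 6,000 foods, 3,558 participants, 4 days) —
about 210,000 consumption records, which simulate and annotate in
seconds. Unit and property tests use reduced worlds (30–800 foods,
40–400 participants) chosen so each check still exercises the relevant
mechanism at meaningful resolution.
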