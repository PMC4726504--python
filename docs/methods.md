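# Methods

This note documents the modelling choices in `nutrisupply`: what each
stage assumes, which parameters matter, what the synthetic data does and
does not emulate, and where the design was genuinely open.

## Scope and units

The pipeline estimates *supplies* — food available for consumption —
not intake. Balance-sheet accounting systematically overstates intake
(no home waste, cooking losses or retention factors are modelled), so
results are best read as upper bounds on potential intake and lower
bounds on deficiency risk. Sodium from added salt is out of scope: only
sodium intrinsic to foods can be captured by this route.

Internal units are fixed: commodity flows in tonnes/year, per-capita
supplies in g/person/day, nutrient densities per 100 g edible portion.
Flow→supply conversion divides by an explicit population table and a
365.25-day year; the day-count convention is a config input
(`days_per_year`) because source datasets are not consistent about it.

## Disaggregation

Child domestic supply is `production + imports − exports` with processed
forms converted to primary equivalent first. Two deliberate choices:

- **Negative balances are clamped to zero** (with a logged warning).
  Re-exporting entrepôts can legitimately show exports exceeding
  production plus imports; every downstream step is multiplicative and
  requires non-negative mass, so the clamp is the least-bad option.
- **Child-level stock or non-food-use data is ignored.** Stocks and
  non-food uses are only credible at the parent level, so they enter
  exclusively through the parent's food/domestic-supply ratio. This
  makes ratio preservation exact: every child's food/domestic ratio
  equals the parent's.

The r² about the 1:1 line is a residual statistic, not a squared
correlation; it is negative whenever residuals exceed the reference
variance and is reported as computed, never floored. Categories that are
nutritionally homogeneous can be passed through undisaggregated via a
per-category flag. Offals are re-derived from meat carcass supplies
(carcass→live→offal factors) because trade-based offal balances are
poor.

## nes correction

The data-quality flag is the disambiguator: *official* nes is genuinely
consumed unlisted food and is retained as its own category;
*estimated*/*imputed* nes is a balancing residual and is redistributed.
*Unofficial* nes is ambiguous; the default retains it with a warning,
and a config switch (`treat_unofficial_as_redistributable`) flips it.

Census-share redistribution, when shares are available, replaces the
within-group split entirely (named supplies plus redistributable nes are
re-split by census production shares); proportional redistribution
otherwise spreads nes pro rata over named supplies. Both conserve group
mass exactly; the census splitter assigns the float rounding residual to
the last food so outputs sum to the total bit-exactly.

The exclusion threshold (default 5 reported categories per group) is a
judgment call, kept configurable. An excluded country-group is dropped
for **all** years: sparse reporting indicts the series, not one year.
Retained nes keeps its own food row; for nutrient matching it receives
the pooled candidate entries of its group's named foods (a
"group-average" candidate set), since no composition table has an entry
for a residual category.

## Edible conversion and processed foods

Plant foods skip the carcass→retail step (farm-to-retail losses are
already embedded in reported supplies) but their basis still advances;
basis transitions are validated to only move primary→retail→edible.
Seafood uses one averaged factor per category (fish classes,
crustaceans, cephalopods, molluscs); all factors are config data, not
code, because the authoritative factor tables are not redistributable.

The refined-flour split runs on the **edible-basis** grain supply
(fortificants are added at milling, after cleaning; composition entries
for flour are per edible flour mass); the order is configurable
(`grain_split_basis`) since sources are silent on it. Flour is a new
food row — `flour + whole ≤ grain`, with equality only at extraction
rate 1; the milling loss leaves the food supply and is tracked in the
mass-loss ledger. Rice is reported in milled weight and is structurally
excluded from the split (constructor-level error).

Cheese entries are divided by the milkfat factor to join the milk
candidate pool; soft fresh cheeses are instead rescaled so their fat
density matches configured local whole-milk fat.

## Monte Carlo nutrient estimation

- **Percentiles** use the linear-interpolation order-statistic
  definition ("type 7", numpy's default), centralised in one function.
- **Draws are independent** across foods and across iterations; no
  candidate choice persists between iterations.
- **Missing nutrient within a candidate**: filled with the candidate-pool
  mean for that food (logged). A nutrient absent from every candidate of
  a food contributes zero (logged). Both are below the granularity the
  uncertainty interval is meant to capture.
- **Reproducibility**: one master seed; each country's substream is
  derived by hashing the country name into the seed sequence, so country
  processing order cannot change results. Identical seed and inputs are
  bit-for-bit reproducible.
- **Age-sex runs share draws across groups**: the candidate ambiguity is
  a property of the food, not the group, so all groups see the same
  per-iteration choice. This keeps group totals comparable and makes
  population-weighted iteration totals reproduce national iteration
  totals exactly.

The default nutrient panel has 23 entries and includes selenium but not
sodium. Source conventions for this panel genuinely disagree (some
enumerate selenium, others sodium); the panel is configurable
(`nutrients` in the config) rather than resolved.

## Fortification

Modelled as a deterministic post-MC shift: guideline levels are fixed
values, not distributions, so sampling them would fabricate uncertainty.
The **lower bound** of a guideline range is used — part of the added
nutrient is lost in processing, storage and transport, so the low end
better reflects the consumed product. Cereal-flour vehicles are gated by
the industrially milled fraction (home and village mills do not
fortify); all other vehicles use their full supply. Mandatory and
voluntary rules both apply by default, with a config filter. The overlay
targets the most recent year only (configurable `target_year`). Because
additions are non-negative and shift all three summary statistics
equally, fortified ≥ unfortified holds for every statistic.

Whether flour fortification should also reach the unprocessed grain
remainder is unstated in guideline sources; this package fortifies the
flour row only (fortificants enter at milling).

## Age-sex disaggregation

The chain is: 2,000 kcal normalization → category intake ratio →
requirement-proportional calorie allocation → de-normalization →
consistency rescale. Choices:

- **34-group layout** = 26 adult groups (5-year brackets, 20–80+, both
  sexes) + 8 child/adolescent brackets. Child groups have no survey
  ratios and take the national average adjusted value; adult-only foods
  (alcohol, stimulants, spices) are zero for them; foods with no
  category match (starchy vegetables, sweeteners, eggs) are uniform
  across all groups.
- **Fatty-acid proxies**: oils and oilseeds map to fatty-acid intake
  ratios (plant omega-3, PUFA, SFA, seafood omega-3) and the ratio is
  applied multiplicatively exactly as for food-group categories. The
  proxy assignment lives in the category-map CSV, not code.
- **Explicit consistency enforcement**: with child groups pinned at
  average values, the ratio+energy chain does not automatically satisfy
  the requirement that population-weighted group supplies equal the
  national supply. A per-food multiplicative rescale is the simplest
  mechanism that enforces it exactly (to 1e-12 relative in tests); it is
  a separate, inspectable stage rather than a hidden adjustment.
- The national calorie supply feeding the normalization is the
  pipeline's own estimate: the Monte Carlo median of calories for that
  country-year.

## Synthetic data

The generator fabricates every input at configurable scale. Quantities
are drawn log-normally (commodity supplies are heavy-tailed); calorie
densities are class-typical (cereals ≈ 350 kcal/100 g, oil ≈ 880, meat ≈
200, fruit ≈ 55, vegetables ≈ 35) so that simulated diets land at
realistic magnitudes of a few thousand kcal/day; other densities are
log-normal around panel-typical scales. Two properties hold by
construction and anchor the test oracles: parent balances equal the sum
of their generated children (so disaggregation must recover r² = 1 to
machine precision), and intake ratios are population-weighted to exactly
1 across adult groups. nes scenarios inject official, estimated/imputed,
or sparse-reporter patterns; the sparse scenario gives one country only
4 named fruit categories, which must trip the exclusion rule.

Default scale (3 countries × 2 years, 8 children per category, ≤3
candidates per food, 1,000 iterations) keeps a full pipeline run within
seconds while exercising every code path; tests use 20–100 iterations
where only structure matters and 10,000 where Monte Carlo accuracy is
itself under test.

What the synthetic world does **not** emulate: real dietary composition
(no country resembles an actual nation), correlated trade structures,
year-over-year autocorrelation, realistic flag mixtures within one
series, or genuine census shares. Passing tests therefore demonstrate
correctness of the accounting and sampling machinery under the stated
invariants — not calibration against any real population.

The hard-coded minimal fixture (`country_x_fixture`) pins the worked
example of the age-sex chain — 30 g/day apples at 3,000 kcal/day
national energy, a +10% fruit group with requirement 2,200 against a
2,500 average — as a permanent regression anchor; its counterpart group
is assigned ratio 0.90 and requirement 2,800 so that ratios weight to 1
and requirements average to 2,500 under equal populations.

## Numerical conventions

- Redistribution and rescaling conserve mass to ≤1e-9 relative
  (redistribution) and 1e-12 relative (consistency enforcement) in the
  property suite; the underlying operations are exact up to float
  arithmetic.
- Degenerate inputs: a single Monte Carlo iteration or single candidates
  per food yield zero-width intervals (valid, tested); zero national
  supply of a food zeroes all group supplies; an all-zero group vector
  against a positive national supply is an error, not a silent fix.
- Every clamp or fallback (negative balance, unofficial nes, missing
  density, pooled nes candidates) emits one structured log warning with
  record identifiers; pipeline runs collect these into the manifest so
  silent data mutation is impossible.

## Known limitations

Supply ≠ intake (see Scope). The uncertainty interval captures only
composition-table heterogeneity — not reporting error in the underlying
balances, conversion-factor uncertainty, or fortification compliance.
Child/adolescent intake ratios are not modelled, only the average-value
assumption. Cooking, retention, and preparation losses are absent by
design.
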