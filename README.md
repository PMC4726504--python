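# nutrisupply

Estimation of national food and nutrient supplies from commodity-balance
data, for nutrition and food-security researchers who need per-capita
supplies of individual foods and micronutrients — with uncertainty — where
only balance-sheet-style statistics exist.

National food balance sheets report production, trade and utilization for
a limited set of broad commodity categories, in primary (farm/carcass/
landed) weight, as national averages, with no micronutrient information.
`nutrisupply` turns such data into:

- per-capita **edible supplies of individual foods** (g/person/day), by
  replicating the balance-sheet method on production and trade data for
  the foods inside each broad category;
- **per-nutrient supply distributions** for a 23-nutrient panel (energy,
  macronutrients, fiber, 3 fatty-acid classes, 8 minerals including
  selenium, 7 vitamins), as a median and 95% uncertainty interval;
- **fortification-augmented supplies** from guideline rule tables; and
- **age-sex-specific supplies** for 26 adult plus 8 child/adolescent
  demographic groups.

## Model

**Disaggregation.** For each food *i* in a broad category *P*, domestic
supply is `D_i = production_i + imports_i − exports_i`, with processed
forms folded back to primary equivalent (`D += factor × processed`).
Non-food uses and stocks are known only at the category level, so each
food inherits the parent's food ratio:

    F_i = D_i × F_P / D_P

Agreement between `Σ_i D_i` and `D_P` is scored with an r² about the 1:1
line, `1 − Σ(ref−model)² / Σ(ref−mean(ref))²` (unbounded below). Offal
supply is re-derived from meat carcass weight via carcass→live→offal
factors, because the trade-based route is unreliable for offals.

**nes correction.** Residual "not elsewhere specified" fruit/vegetable
supplies are split by data-quality flag: official nes is a real category
and is retained; estimated/imputed nes is a balancing artifact and is
redistributed over the named foods (census production shares where
available, otherwise proportionally). Countries naming ≤ 5 categories in
a group are excluded as too sparse to trust.

**Edible conversion.** Meat and seafood convert carcass/landed weight to
retail weight, then every food loses its inedible discard fraction:
`edible = primary × c2r × (1 − discard)`. A region-specific share of
wheat, maize, millet and sorghum becomes refined flour (a new food row)
at the grain-to-flour extraction rate; rice is already reported milled
and is never split. Cheese composition entries are folded to whole-milk
equivalent by the milkfat factor.

**Monte Carlo nutrient estimation.** Each food matches *all* equally good
composition-table candidates through a regional fallback chain (regional
table → older continental table → US reference → across-table average).
Per iteration, one candidate per food is drawn uniformly; the national
total per nutrient is `Σ_i supply_i × density_i / 100`. Medians and
2.5/97.5 percentiles over (by default) 1,000 iterations give the 95%
uncertainty interval, which reflects composition heterogeneity.

**Fortification.** A deterministic overlay for the most recent year:
`addition = vehicle supply (kg/day) × lower guideline bound (per kg) ×
industrially-milled fraction` (the milling gate applies to cereal flours
only), shifting median and both bounds equally.

**Age-sex disaggregation.** Supplies are normalized to a 2,000 kcal diet
(`× 2000/E_nat`), scaled by each group's relative-intake ratio for the
food's dietary category, de-normalized with group calorie supplies
allocated in proportion to energy requirements (`E_g = req_g ×
E_nat/avg_req`), and finally rescaled per food so population-weighted
group supplies reproduce the national supply exactly.

## Worked example

No external data is needed — the `synthetic` module generates a complete,
seeded input bundle:

```python
from nutrisupply import FixtureSpec, PipelineConfig, generate_world, run_pipeline
import pandas as pd

generate_world(FixtureSpec(seed=42, nes_scenario="estimated")).write("bundle")
cfg = PipelineConfig(input_dir="bundle", out_dir="out", seed=42, n_iter=1000)
manifest = run_pipeline(cfg)

national = pd.read_csv("out/nutrients_national.csv")
print(national.query("country=='C0' and year==2011 and nutrient=='calories'"))
```

which prints (numbers from this exact run):

```
C0 2011 energy supply: 3573 kcal/day (95% UI 3164-4043)
C0 2011 iron: 17.9 mg/day unfortified, 22.5 mg/day with fortification
C0 wheat flour, women 50-54: 182 g/day; men 20-24: 331 g/day
```

The energy interval spans ~±12% because each synthetic food has up to
three composition candidates; iron rises by the flour and oil
fortification rules scaled by the industrially milled flour share; the
two demographic groups differ through their intake ratios and energy
requirements.

The same run is available from the shell:

```sh
nutrisupply fixtures --seed 42 --scenario estimated --out-dir bundle
nutrisupply run --in-dir bundle --out-dir out --seed 42 --n-iter 1000
nutrisupply validate --in-dir bundle --out-dir out   # r² report
```

Stage subcommands (`disaggregate`, `fv-correct`, `edible`, `nutrients`,
`fortify`, `agesex`) run the pipeline stepwise over the same files.

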