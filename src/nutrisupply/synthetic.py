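"""Seeded synthetic input bundles for every pipeline stage.

No stage of the pipeline requires real agency data: this module fabricates
schema-valid commodity flows, category maps, conversion factors,
composition tables, relative-intake ratios, demographics and fortification
rules at configurable scale. Quantities are drawn log-normally to mimic
the heavy-tailed spread of real commodity supplies.

Two construction guarantees make the bundles useful as test oracles:
parent-category flows equal the sum of their generated child flows (so
disaggregation must recover the parent totals exactly, r² = 1), and
relative-intake ratios are population-weighted to mean 1 across adult
groups (the defining property of ratios about a national average).

``country_x_fixture`` is a hard-coded minimal world encoding the standard
worked example of the age-sex chain (30 g/day of apples, 3,000 kcal/day
national energy, a +10% fruit group, requirements 2,200 vs 2,500 average)
so those numbers stay a permanent regression anchor.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .age_sex import AgeSexGroup
from .fbs_io import CommodityFlowRecord, DataFlag, read_flow_table, write_flow_table
from .nutrient_mc import NUTRIENT_UNITS, NUTRIENTS, CompositionEntry

#: Typical per-100 g density scale for each nutrient (geometric centre of
#: the synthetic draw). Chosen to span the magnitude range of real tables.
_DENSITY_SCALE: dict[str, float] = {
    "calories": 90.0, "fat": 2.0, "protein": 3.0, "carbohydrates": 15.0,
    "dietary_fiber": 1.5, "vitamin_c": 20.0, "thiamin": 0.1, "riboflavin": 0.1,
    "niacin": 1.5, "vitamin_b6": 0.2, "vitamin_a": 30.0, "folate": 30.0,
    "calcium": 30.0, "iron": 1.5, "zinc": 1.0, "potassium": 250.0,
    "copper": 0.15, "magnesium": 25.0, "phosphorus": 80.0, "selenium": 5.0,
    "saturated_fa": 0.8, "monounsaturated_fa": 0.8, "polyunsaturated_fa": 0.8,
}

NES_SCENARIOS = ("none", "official", "estimated", "sparse")


def _calorie_base(food: str) -> float:
    """Class-typical energy density (kcal/100 g edible) for synthetic foods."""
    if food in ("wheat", "maize") or food.startswith("cereals_other"):
        return 350.0
    if food.endswith("_flour"):
        return 360.0
    if food == "vegetable_oil":
        return 880.0
    if food.startswith("meat_") or food == "offals":
        return 200.0
    if food.startswith("fruit"):
        return 55.0
    if food.startswith("vegetables"):
        return 35.0
    return {"alcohol": 70.0, "potatoes": 75.0, "eggs": 140.0}.get(food, 90.0)

_TABLE_FILES = {
    "category_map": "category_map.csv",
    "offal_factors": "offal_factors.csv",
    "edible_factors": "edible_factors.csv",
    "grain_processing": "grain_processing.csv",
    "country_region": "country_region.csv",
    "composition": "composition.csv",
    "gdd_map": "gdd_map.csv",
    "gdd_ratios": "gdd_ratios.csv",
    "demographics": "demographics.csv",
    "population": "population.csv",
    "fortification_rules": "fortification_rules.csv",
    "industrial_fractions": "industrial_fractions.csv",
    "nes_flags": "nes_flags.csv",
    "food_groups": "food_groups.csv",
}


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the synthetic world generator."""

    n_countries: int = 3
    n_children_per_parent: int = 8
    years: tuple[int, ...] = (2010, 2011)
    seed: int = 0
    nes_scenario: str = "none"
    candidate_counts: tuple[int, ...] = (1, 2, 3)
    ratio_dispersion: float = 0.15

    def __post_init__(self) -> None:
        if self.n_countries < 1 or self.n_children_per_parent < 1 or not self.years:
            raise ValueError("fixture spec counts must be >= 1 and years non-empty")
        if self.nes_scenario not in NES_SCENARIOS:
            raise ValueError(f"unknown nes_scenario {self.nes_scenario!r}")
        if not self.candidate_counts or min(self.candidate_counts) < 1:
            raise ValueError("candidate_counts must be non-empty positive integers")
        if self.ratio_dispersion < 0:
            raise ValueError("ratio_dispersion must be >= 0")


@dataclasses.dataclass
class WorldBundle:
    """Full set of input tables for one pipeline run."""

    child_flows: list[CommodityFlowRecord]
    parent_flows: list[CommodityFlowRecord]
    category_map: pd.DataFrame  # parent, child, processed_form, factor, disaggregate
    offal_factors: pd.DataFrame  # animal_type, carcass_to_live, live_to_offal
    edible_factors: pd.DataFrame  # food, carcass_to_retail, discard_fraction
    grain_processing: pd.DataFrame  # grain, region, processed_fraction, extraction_rate
    country_region: pd.DataFrame  # country, region, table_chain ("a|b|c")
    composition: pd.DataFrame  # table_id, food, entry, nutrient, density_per_100g, unit
    gdd_map: pd.DataFrame  # food, mapping
    gdd_ratios: pd.DataFrame  # country, category, group_id, ratio
    demographics: pd.DataFrame  # country, group_id, sex, age_low, age_high, population, energy_requirement
    population: pd.DataFrame  # country, population
    fortification_rules: pd.DataFrame  # country, vehicle, nutrient, amount_low, amount_high, status
    industrial_fractions: pd.DataFrame  # country, vehicle, fraction
    nes_flags: pd.DataFrame  # country, food, food_group, flag
    food_groups: pd.DataFrame  # food, food_group

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_flow_table(self.child_flows, out / "flows_children.csv")
        write_flow_table(self.parent_flows, out / "flows_parents.csv")
        for attr, fname in _TABLE_FILES.items():
            getattr(self, attr).to_csv(out / fname, index=False)

    @classmethod
    def load(cls, in_dir: str | Path) -> "WorldBundle":
        d = Path(in_dir)
        kwargs = {
            "child_flows": read_flow_table(d / "flows_children.csv"),
            "parent_flows": read_flow_table(d / "flows_parents.csv"),
        }
        for attr, fname in _TABLE_FILES.items():
            kwargs[attr] = pd.read_csv(d / fname, keep_default_na=False, na_values=[""])
        return cls(**kwargs)

    def groups_for(self, country: str) -> list[AgeSexGroup]:
        sub = self.demographics[self.demographics["country"] == country]
        groups = []
        for r in sub.itertuples(index=False):
            high = None if str(r.age_high) in ("", "nan") else int(float(r.age_high))
            groups.append(
                AgeSexGroup(str(r.sex), int(r.age_low), high,
                            float(r.population), float(r.energy_requirement))
            )
        return groups


def _flow(country: str, year: int, commodity: str, production: float,
          imports: float, exports: float, flag: DataFlag = DataFlag.OFFICIAL,
          **extra: float) -> CommodityFlowRecord:
    rec = CommodityFlowRecord(country, year, commodity,
                              production=production, imports=imports, exports=exports)
    for k, v in extra.items():
        setattr(rec, k, v)
    for element in ("production", "imports", "exports", *extra):
        rec.flags[element] = flag
    return rec


def _split_trade(rng: np.random.Generator, domestic: float) -> tuple[float, float, float]:
    """Decompose a target domestic supply into production/imports/exports."""
    exports = domestic * rng.uniform(0.0, 0.25)
    production = (domestic + exports) * rng.uniform(0.6, 0.95)
    imports = domestic + exports - production
    return production, imports, exports


def generate_world(spec: FixtureSpec) -> WorldBundle:
    """Generate a deterministic, schema-valid input bundle.

    Parent balances are built from the generated children, so summed child
    domestic supplies equal the parent domestic supply exactly for every
    disaggregated category.
    """
    rng = np.random.default_rng(spec.seed)
    countries = [f"C{i}" for i in range(spec.n_countries)]
    years = list(spec.years)
    latest = max(years)

    disagg_parents = {
        "fruit_other": "fruit",
        "vegetables_other": "vegetable",
        "cereals_other": None,
        "meat_other": None,
    }
    animal_types = ("bovine", "pig", "poultry")
    standalone = ("wheat", "maize", "vegetable_oil", "alcohol", "potatoes", "eggs")

    cat_rows: list[tuple[str, str, str, float, str]] = []
    children_of: dict[str, list[str]] = {}
    for parent in disagg_parents:
        if parent == "meat_other":
            kids = [f"meat_{a}" for a in animal_types]
        else:
            kids = [f"{parent}_c{i}" for i in range(spec.n_children_per_parent)]
        children_of[parent] = kids
        for child in kids:
            cat_rows.append((parent, child, "", 1.0, "yes"))
    # one processed form per fruit/vegetable parent, folded to its first child
    proc_factor: dict[str, tuple[str, str, float]] = {}
    for parent in ("fruit_other", "vegetables_other"):
        child = children_of[parent][0]
        form = f"{child}_dried"
        factor = float(rng.uniform(2.5, 4.0))
        proc_factor[parent] = (form, child, factor)
        cat_rows.append((parent, child, form, factor, "yes"))
    cat_rows.append(("offals", "offals", "", 1.0, "yes"))
    for parent in standalone:
        cat_rows.append((parent, parent, "", 1.0, "no"))
    nes_food = "fruit_nes"
    if spec.nes_scenario != "none":
        children_of["fruit_other"] = children_of["fruit_other"] + [nes_food]
        cat_rows.append(("fruit_other", nes_food, "", 1.0, "yes"))
    category_map = pd.DataFrame(
        cat_rows, columns=["parent", "child", "processed_form", "factor", "disaggregate"]
    )

    offal_factors = pd.DataFrame(
        [(f"meat_{a}", float(rng.uniform(1.6, 2.4)), float(rng.uniform(0.03, 0.08)))
         for a in animal_types],
        columns=["animal_type", "carcass_to_live", "live_to_offal"],
    )

    offal_conv = {
        str(r.animal_type): float(r.carcass_to_live) * float(r.live_to_offal)
        for r in offal_factors.itertuples(index=False)
    }

    child_flows: list[CommodityFlowRecord] = []
    parent_flows: list[CommodityFlowRecord] = []
    nes_flag_rows: list[tuple[str, str, str, str]] = []
    sparse_country = countries[0]

    for country in countries:
        for year in years:
            meat_dom: dict[str, float] = {}
            for parent, kids in children_of.items():
                dom: dict[str, float] = {}
                for k, child in enumerate(kids):
                    d = float(rng.lognormal(np.log(5e4), 0.8))
                    if child == nes_food:
                        if spec.nes_scenario == "official":
                            flag = DataFlag.OFFICIAL
                        elif spec.nes_scenario in ("estimated", "sparse"):
                            flag = DataFlag.ESTIMATED if year == latest else DataFlag.IMPUTED
                        d *= 4.0  # nes dominates, mimicking sparse reporters
                        if year == latest:
                            nes_flag_rows.append((country, nes_food, "fruit", flag.value))
                        p, i, e = _split_trade(rng, d)
                        child_flows.append(_flow(country, year, child, p, i, e, flag))
                        dom[child] = d
                        continue
                    if (
                        spec.nes_scenario == "sparse"
                        and country == sparse_country
                        and parent == "fruit_other"
                        and k >= 4
                    ):
                        d = 0.0  # sparse reporter: at most 4 named fruit categories
                    form_info = proc_factor.get(parent)
                    if form_info is not None and child == form_info[1] and d > 0:
                        form, _, factor = form_info
                        processed_primary = 0.3 * d
                        p, i, e = _split_trade(rng, processed_primary / factor)
                        child_flows.append(_flow(country, year, form, p, i, e))
                        d_primary = d - processed_primary
                    else:
                        d_primary = d
                    p, i, e = _split_trade(rng, d_primary)
                    child_flows.append(_flow(country, year, child, p, i, e))
                    dom[child] = d
                total = sum(dom.values())
                food_ratio = float(rng.uniform(0.55, 0.85))
                parent_flows.append(
                    _flow(country, year, parent, total, 0.0, 0.0,
                          food=total * food_ratio, feed=total * (1.0 - food_ratio))
                )
                if parent == "meat_other":
                    meat_dom = dict(dom)
            # offal parent balance consistent with the meat-based recalculation
            offal_total = sum(meat_dom[a] * offal_conv[a] for a in meat_dom)
            parent_flows.append(
                _flow(country, year, "offals", offal_total, 0.0, 0.0,
                      food=offal_total * 0.8, feed=offal_total * 0.2)
            )
            for food in standalone:
                d = float(rng.lognormal(np.log(8e5 if food in ("wheat", "maize") else 1e5), 0.4))
                parent_flows.append(
                    _flow(country, year, food, d, 0.0, 0.0, food=d * float(rng.uniform(0.6, 0.9)))
                )

    all_foods = sorted(
        {c for kids in children_of.values() for c in kids} | set(standalone) | {"offals"}
    )
    flour_foods = ["wheat_flour", "maize_flour"]

    # --- edible factors ------------------------------------------------
    ef_rows = []
    for food in all_foods:
        if food.startswith("meat_") or food == "offals":
            ef_rows.append((food, float(rng.uniform(0.6, 0.8)), float(rng.uniform(0.1, 0.3))))
        elif food in ("vegetable_oil", "alcohol", "wheat", "maize"):
            ef_rows.append((food, "", 0.0))
        else:
            ef_rows.append((food, "", float(rng.uniform(0.05, 0.35))))
    edible_factors = pd.DataFrame(
        ef_rows, columns=["food", "carcass_to_retail", "discard_fraction"]
    )

    regions = [f"R{i % 2}" for i in range(spec.n_countries)]
    grain_processing = pd.DataFrame(
        [(g, r, float(rng.uniform(0.5, 0.9)), float(rng.uniform(0.72, 0.82)))
         for g in ("wheat", "maize") for r in sorted(set(regions))],
        columns=["grain", "region", "processed_fraction", "extraction_rate"],
    )

    chains = {"R0": "regional_r0|legacy_continental|reference_us",
              "R1": "regional_r1|reference_us"}
    country_region = pd.DataFrame(
        [(c, r, chains[r]) for c, r in zip(countries, regions)],
        columns=["country", "region", "table_chain"],
    )

    # --- composition tables --------------------------------------------
    comp_rows = []
    mc_foods = [f for f in all_foods if f != nes_food] + flour_foods
    table_presence = {"regional_r0": 0.7, "regional_r1": 0.7,
                      "legacy_continental": 0.4, "reference_us": 0.95}
    for food in mc_foods:
        base = {n: _DENSITY_SCALE[n] * float(rng.lognormal(0.0, 0.5)) for n in NUTRIENTS}
        base["calories"] = _calorie_base(food) * float(rng.lognormal(0.0, 0.1))
        if food == "vegetable_oil":
            base["fat"] = 99.0
            base["carbohydrates"] = 0.0
            base["protein"] = 0.0
        present_somewhere = False
        for table_id, p in table_presence.items():
            if rng.uniform() > p and table_id != "reference_us":
                continue
            if table_id == "reference_us" and present_somewhere and rng.uniform() > p:
                continue
            present_somewhere = True
            n_cand = int(rng.choice(spec.candidate_counts))
            for entry in range(n_cand):
                for n in NUTRIENTS:
                    dens = base[n] * float(rng.lognormal(0.0, 0.2))
                    comp_rows.append(
                        (table_id, food, f"e{entry}", n, dens, NUTRIENT_UNITS[n])
                    )
    composition = pd.DataFrame(
        comp_rows,
        columns=["table_id", "food", "entry", "nutrient", "density_per_100g", "unit"],
    )

    # --- dietary-category map and ratios --------------------------------
    map_rows = []
    for food in mc_foods + ([nes_food] if spec.nes_scenario != "none" else []):
        if food.startswith("fruit"):
            mapping = "fruit"
        elif food.startswith("vegetables_other"):
            mapping = "vegetable"
        elif food.startswith("cereals_other") or food in ("wheat", "maize", *flour_foods):
            mapping = "cereal"
        elif food.startswith("meat_") or food == "offals":
            mapping = "meat"
        elif food == "vegetable_oil":
            mapping = "fatty_acid_proxy:pufa"
        elif food == "alcohol":
            mapping = "adult_only"
        else:  # potatoes, eggs: starchy vegetables / eggs take the average
            mapping = "uniform"
        map_rows.append((food, mapping))
    gdd_map = pd.DataFrame(map_rows, columns=["food", "mapping"])

    # --- demographics: 8 child/adolescent + 26 adult groups -------------
    demo_rows = []
    group_defs: list[tuple[str, int, int | None]] = []
    for sex in ("female", "male"):
        for lo in range(0, 20, 5):
            group_defs.append((sex, lo, lo + 4))
        for lo in range(20, 80, 5):
            group_defs.append((sex, lo, lo + 4))
        group_defs.append((sex, 80, None))
    for country in countries:
        for sex, lo, hi in group_defs:
            pop = float(rng.lognormal(np.log(2e5 if lo < 60 else 8e4), 0.3))
            if lo < 20:
                req = float(rng.uniform(1300.0, 2200.0))
            else:
                base_req = 2600.0 if sex == "male" else 2100.0
                req = base_req * float(rng.uniform(0.9, 1.05)) - 4.0 * max(0, lo - 20)
            demo_rows.append((country, sex, lo, "" if hi is None else hi, pop, req))
    demographics = pd.DataFrame(
        demo_rows,
        columns=["country", "sex", "age_low", "age_high", "population", "energy_requirement"],
    )
    demographics["group_id"] = [
        AgeSexGroup(r.sex, int(r.age_low), None if r.age_high == "" else int(r.age_high),
                    float(r.population), float(r.energy_requirement)).group_id
        for r in demographics.itertuples(index=False)
    ]
    demographics = demographics[
        ["country", "group_id", "sex", "age_low", "age_high", "population", "energy_requirement"]
    ]

    population = pd.DataFrame(
        [(c, float(demographics[demographics["country"] == c]["population"].sum()))
         for c in countries],
        columns=["country", "population"],
    )

    ratio_rows = []
    categories = ("fruit", "vegetable", "cereal", "meat", "pufa")
    for country in countries:
        sub = demographics[demographics["country"] == country]
        adult = sub[sub["age_low"] >= 20]
        pops = adult["population"].to_numpy(dtype=float)
        for cat in categories:
            raw = rng.lognormal(0.0, spec.ratio_dispersion, size=len(adult))
            raw = raw / (np.average(raw, weights=pops))  # weighted mean exactly 1
            for gid, r in zip(adult["group_id"], raw):
                ratio_rows.append((country, cat, gid, float(r)))
    gdd_ratios = pd.DataFrame(ratio_rows, columns=["country", "category", "group_id", "ratio"])

    # --- fortification ---------------------------------------------------
    fort_rows, frac_rows = [], []
    for country in countries:
        fort_rows.append((country, "wheat_flour", "iron", 30.0, 45.0, "mandatory"))
        fort_rows.append((country, "wheat_flour", "folate", 1300.0, 2600.0, "mandatory"))
        fort_rows.append((country, "vegetable_oil", "vitamin_a", 6000.0, 9000.0, "voluntary"))
        frac_rows.append((country, "wheat_flour", float(rng.uniform(0.3, 0.95))))
    fortification_rules = pd.DataFrame(
        fort_rows, columns=["country", "vehicle", "nutrient", "amount_low", "amount_high", "status"]
    )
    industrial_fractions = pd.DataFrame(frac_rows, columns=["country", "vehicle", "fraction"])

    nes_flags = pd.DataFrame(nes_flag_rows, columns=["country", "food", "food_group", "flag"])

    fg_rows = [(f, "fruit") for f in children_of["fruit_other"]]
    fg_rows += [(f, "vegetable") for f in children_of["vegetables_other"]]
    food_groups = pd.DataFrame(fg_rows, columns=["food", "food_group"])

    return WorldBundle(
        child_flows=child_flows,
        parent_flows=parent_flows,
        category_map=category_map,
        offal_factors=offal_factors,
        edible_factors=edible_factors,
        grain_processing=grain_processing,
        country_region=country_region,
        composition=composition,
        gdd_map=gdd_map,
        gdd_ratios=gdd_ratios,
        demographics=demographics,
        population=population,
        fortification_rules=fortification_rules,
        industrial_fractions=industrial_fractions,
        nes_flags=nes_flags,
        food_groups=food_groups,
    )


@dataclasses.dataclass(frozen=True)
class CountryXFixture:
    """The minimal worked-example world: one country, two foods, two groups.

    Encodes: apples 30 g/day, national energy 3,000 kcal/day, a women-50–54
    group whose fruit intake runs 10% above the national average and whose
    energy requirement is 2,200 kcal/day against a population-weighted
    average requirement of 2,500 kcal/day, and a potato supply of
    114 g/day with a single 70 kcal/100 g composition candidate.
    """

    apples_g_day: float = 30.0
    national_energy_kcal: float = 3000.0
    potatoes_g_day: float = 114.0

    @property
    def groups(self) -> list[AgeSexGroup]:
        # equal populations; requirements 2200/2800 average to 2500
        return [
            AgeSexGroup("female", 50, 54, 1000.0, 2200.0),
            AgeSexGroup("male", 50, 54, 1000.0, 2800.0),
        ]

    @property
    def gdd_map(self) -> dict[str, str]:
        return {"apples": "fruit", "potatoes": "uniform"}

    @property
    def ratios(self) -> dict[tuple[str, str], float]:
        # fruit ratios population-weight to 1: (1.10 + 0.90) / 2
        return {("fruit", "F50_54"): 1.10, ("fruit", "M50_54"): 0.90}

    @property
    def national_supplies(self) -> dict[str, float]:
        return {"apples": self.apples_g_day, "potatoes": self.potatoes_g_day}

    @property
    def candidates(self) -> dict[str, list[CompositionEntry]]:
        return {
            "apples": [CompositionEntry("reference_us", "apples", {"calories": 52.0})],
            "potatoes": [CompositionEntry("reference_us", "potatoes", {"calories": 70.0})],
        }


def country_x_fixture() -> CountryXFixture:
    """The hard-coded worked-example bundle (see :class:`CountryXFixture`)."""
    return CountryXFixture()

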