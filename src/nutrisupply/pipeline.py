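"""End-to-end orchestration: disaggregate → correct → edible → MC → fortify → age-sex.

Each stage is a pure function of (input tables, config, seed); re-running
with identical inputs reproduces identical outputs byte for byte. Every
stage's output frame is persisted so intermediate states can be inspected,
and a JSON manifest records the config hash, per-stage record counts and
every warning emitted during the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from pathlib import Path

import pandas as pd

from . import age_sex as asx
from . import fortification as fort
from .disaggregation import (
    CategoryMap,
    OffalFactors,
    disaggregate_table,
    to_per_capita,
)
from .edible_processing import EdibleFactors, EdibleResult, GrainProcessing, edible_table
from .fbs_io import DataFlag, PipelineConfig, WarningCollector, flows_to_frame
from .fv_correction import correct_group
from .nutrient_mc import (
    NUTRIENT_UNITS,
    NUTRIENTS,
    candidates_for,
    composition_index,
    country_rng,
    national_nutrients,
)
from .synthetic import WorldBundle

log = logging.getLogger("nutrisupply")

STAGE_FILES = {
    "disaggregate": ("supplies_primary.csv", "validation_r2.csv"),
    "fv_correct": ("supplies_corrected.csv", "exclusions.csv"),
    "edible": ("supplies_edible.csv", "mass_losses.csv"),
    "nutrients": ("nutrients_national.csv",),
    "fortify": ("nutrients_fortified.csv",),
    "agesex": ("group_foods.csv", "group_nutrients.csv"),
}


@dataclasses.dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    seed: int
    stages: list[dict]
    outputs: dict[str, str]
    warnings: list[str]

    def write(self, path: str | Path) -> None:
        """Atomic write: serialize to a temp file, then rename into place."""
        path = Path(path)
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(payload, encoding="utf-8")
        os.replace(tmp, path)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()


def _category_maps(bundle: WorldBundle) -> list[CategoryMap]:
    maps = []
    for parent, grp in bundle.category_map.groupby("parent", sort=True):
        children = tuple(dict.fromkeys(str(c) for c in grp["child"]))
        factors = {}
        for r in grp.itertuples(index=False):
            form = str(r.processed_form)
            if form:
                factors[form] = (str(r.child), float(r.factor))
        disagg = str(grp["disaggregate"].iloc[0]).lower() in ("yes", "true", "1")
        maps.append(CategoryMap(str(parent), children, factors, disagg))
    return maps


def _offal_factors(bundle: WorldBundle) -> dict[str, OffalFactors]:
    return {
        str(r.animal_type): OffalFactors(
            str(r.animal_type), float(r.carcass_to_live), float(r.live_to_offal)
        )
        for r in bundle.offal_factors.itertuples(index=False)
    }


def stage_disaggregate(
    bundle: WorldBundle, days_per_year: float = 365.25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand parent balances into per-capita child supplies (primary basis)."""
    result = disaggregate_table(
        flows_to_frame(bundle.child_flows),
        flows_to_frame(bundle.parent_flows),
        _category_maps(bundle),
        offal_factors=_offal_factors(bundle) or None,
        offal_parent="offals",
        meat_parent="meat_other",
    )
    population = {
        str(r.country): float(r.population) for r in bundle.population.itertuples(index=False)
    }
    supplies = to_per_capita(result.supplies, population, days_per_year)
    return supplies, result.report


def stage_fv_correct(
    bundle: WorldBundle,
    supplies: pd.DataFrame,
    threshold: int = 5,
    treat_unofficial_as_redistributable: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve nes fruit/vegetable supplies and apply the exclusion rule.

    Redistribution runs in every country-year-group that carries flagged
    nes supplies. An excluded country-group is dropped from the corrected
    table for all years (sparse reporting voids the whole series, not one
    year), and reported in the exclusion frame.
    """
    members: dict[str, list[str]] = {}
    for r in bundle.food_groups.itertuples(index=False):
        members.setdefault(str(r.food_group), []).append(str(r.food))
    nes_by_cg: dict[tuple[str, str], dict[str, DataFlag]] = {}
    for r in bundle.nes_flags.itertuples(index=False):
        nes_by_cg.setdefault((str(r.country), str(r.food_group)), {})[str(r.food)] = DataFlag(
            str(r.flag)
        )

    out = supplies.copy()
    excl_rows: list[tuple[str, str, int, str]] = []
    dropped: set[tuple[str, str]] = set()
    for (country, group), nes_flags in sorted(nes_by_cg.items()):
        group_foods = members.get(group, [])
        gc = None
        for year in sorted(out["year"].unique()):
            mask = (
                (out["country"] == country)
                & (out["year"] == year)
                & (out["food"].isin(group_foods))
            )
            sub = out[mask]
            if sub.empty:
                continue
            amounts = {str(r.food): float(r.amount_g_day) for r in sub.itertuples(index=False)}
            gc = correct_group(
                country, group, amounts, nes_flags,
                threshold=threshold,
                treat_unofficial_as_redistributable=treat_unofficial_as_redistributable,
            )
            if gc.decision == "exclude":
                dropped.add((country, group))
                excl_rows.append(
                    (country, group, gc.assessment.n_reported_categories, "exclude")
                )
                break
            corrected = dict(gc.corrected)
            if gc.retained_nes > 0:
                # retained (official/unofficial) nes keeps its own category
                for food, flag in nes_flags.items():
                    if flag in (DataFlag.OFFICIAL, DataFlag.UNOFFICIAL):
                        corrected[food] = corrected.get(food, 0.0) + amounts.get(food, 0.0)
            for food, amount in corrected.items():
                fmask = mask & (out["food"] == food)
                out.loc[fmask, "amount_g_day"] = amount
            gone = [f for f in amounts if f not in corrected]
            if gone:
                out = out[~(mask & out["food"].isin(gone))]
        else:
            if gc is not None:
                excl_rows.append(
                    (country, group, gc.assessment.n_reported_categories, "retain")
                )
    for country, group in sorted(dropped):
        out = out[
            ~((out["country"] == country) & (out["food"].isin(members.get(group, []))))
        ]
    exclusions = pd.DataFrame(
        excl_rows, columns=["country", "food_group", "n_categories", "decision"]
    )
    return out.reset_index(drop=True), exclusions


def _edible_inputs(bundle: WorldBundle):
    factors: dict[str, EdibleFactors] = {}
    for r in bundle.edible_factors.itertuples(index=False):
        c2r = None if str(r.carcass_to_retail) in ("", "nan") else float(r.carcass_to_retail)
        factors[str(r.food)] = EdibleFactors(str(r.food), c2r, float(r.discard_fraction))
    grains = {
        (str(r.grain), str(r.region)): GrainProcessing(
            str(r.grain), str(r.region), float(r.processed_fraction), float(r.extraction_rate)
        )
        for r in bundle.grain_processing.itertuples(index=False)
    }
    regions = {
        str(r.country): str(r.region) for r in bundle.country_region.itertuples(index=False)
    }
    return factors, grains, regions


def stage_edible(bundle: WorldBundle, supplies: pd.DataFrame) -> EdibleResult:
    """Primary → edible conversion plus the refined-flour split."""
    factors, grains, regions = _edible_inputs(bundle)
    return edible_table(supplies, factors, grains, regions)


def _mc_inputs(bundle: WorldBundle):
    tables = composition_index(bundle.composition)
    region_map = {
        str(r.country): str(r.table_chain).split("|")
        for r in bundle.country_region.itertuples(index=False)
    }
    pool: dict[str, list[str]] = {}
    members: dict[str, list[str]] = {}
    for r in bundle.food_groups.itertuples(index=False):
        members.setdefault(str(r.food_group), []).append(str(r.food))
    for r in bundle.nes_flags.itertuples(index=False):
        food = str(r.food)
        pool[food] = [f for f in members.get(str(r.food_group), []) if f != food]
    return tables, region_map, pool


def stage_nutrients(
    bundle: WorldBundle,
    edible: pd.DataFrame,
    n_iter: int,
    seed: int,
    nutrients: tuple[str, ...] = NUTRIENTS,
) -> pd.DataFrame:
    """National Monte Carlo nutrient summaries per country-year."""
    tables, region_map, pool = _mc_inputs(bundle)
    return national_nutrients(
        edible, tables, region_map, n_iter, seed, nutrients, pool_fallback=pool
    )


def stage_fortify(
    bundle: WorldBundle,
    national: pd.DataFrame,
    edible: pd.DataFrame,
    target_year: int | None = None,
    include_voluntary: bool = True,
) -> pd.DataFrame:
    """Deterministic fortification overlay for the target year."""
    rules = [
        fort.FortificationRule(
            str(r.country), str(r.vehicle), str(r.nutrient),
            float(r.amount_low), float(r.amount_high), str(r.status),
        )
        for r in bundle.fortification_rules.itertuples(index=False)
    ]
    fractions = {
        (str(r.country), str(r.vehicle)): float(r.fraction)
        for r in bundle.industrial_fractions.itertuples(index=False)
    }
    return fort.apply_fortification(
        national, edible, rules, fractions, target_year, include_voluntary
    )


def stage_agesex(
    bundle: WorldBundle,
    edible: pd.DataFrame,
    national: pd.DataFrame,
    n_iter: int,
    seed: int,
    target_year: int | None = None,
    nutrients: tuple[str, ...] = NUTRIENTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Age-sex food supplies and per-group nutrient summaries, target year only.

    National calorie supply for the normalization is the model's own
    estimate: the Monte Carlo median of calories for that country-year.
    """
    if target_year is None:
        target_year = int(edible["year"].max())
    tables, region_map, pool = _mc_inputs(bundle)
    gdd_map = {str(r.food): str(r.mapping) for r in bundle.gdd_map.itertuples(index=False)}
    food_rows, nutr_rows = [], []
    year_supplies = edible[edible["year"] == target_year]
    for country in sorted(year_supplies["country"].unique()):
        cs = year_supplies[year_supplies["country"] == country]
        supplies = {str(r.food): float(r.amount_g_day) for r in cs.itertuples(index=False)}
        cal = national[
            (national["country"] == country)
            & (national["year"] == target_year)
            & (national["nutrient"] == "calories")
        ]
        if cal.empty:
            raise ValueError(f"no national calorie estimate for {country}/{target_year}")
        national_energy = float(cal["median"].iloc[0])
        groups = bundle.groups_for(str(country))
        ratios = {
            (str(r.category), str(r.group_id)): float(r.ratio)
            for r in bundle.gdd_ratios[bundle.gdd_ratios["country"] == country].itertuples(
                index=False
            )
        }
        gf = asx.group_food_supplies(supplies, national_energy, groups, gdd_map, ratios)
        for food in gf.index:
            for gid in gf.columns:
                food_rows.append((country, target_year, food, gid, float(gf.loc[food, gid])))
        cand = {
            f: candidates_for(f, str(country), tables, region_map, pool) for f in gf.index
        }
        summaries = asx.group_nutrients(
            gf, cand, n_iter, country_rng(seed, f"{country}/agesex"), nutrients
        )
        for gid, per_nutrient in summaries.items():
            for n in nutrients:
                s = per_nutrient[n]
                nutr_rows.append(
                    (country, target_year, gid, n, NUTRIENT_UNITS.get(n, ""),
                     s.median, s.lower_95, s.upper_95)
                )
    group_foods = pd.DataFrame(
        food_rows, columns=["country", "year", "food", "group_id", "amount_g_day"]
    )
    group_nutrients = pd.DataFrame(
        nutr_rows,
        columns=["country", "year", "group_id", "nutrient", "unit",
                 "median", "lower_95", "upper_95"],
    )
    return group_foods, group_nutrients


def run_pipeline(config: PipelineConfig, bundle: WorldBundle | None = None) -> RunManifest:
    """Execute all stages in order and persist every stage output.

    Stage order: disaggregate → fv_correct → edible → nutrients → fortify
    → agesex. Returns the manifest (also written to ``manifest.json``).
    """
    config.validate()
    if bundle is None:
        bundle = WorldBundle.load(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collector = WarningCollector()
    log.addHandler(collector)
    nutrients = tuple(config.nutrients) if config.nutrients else NUTRIENTS
    stages: list[dict] = []
    outputs: dict[str, str] = {}

    def persist(stage: str, frames: tuple[pd.DataFrame, ...]) -> None:
        names = STAGE_FILES[stage]
        counts = {}
        for name, frame in zip(names, frames):
            path = out_dir / name
            frame.to_csv(path, index=False)
            outputs[name] = str(path)
            counts[name] = int(len(frame))
        stages.append({"stage": stage, "records": counts})

    try:
        supplies, report = stage_disaggregate(bundle, config.days_per_year)
        persist("disaggregate", (supplies, report))

        corrected, exclusions = stage_fv_correct(
            bundle, supplies, config.exclusion_threshold,
            config.treat_unofficial_as_redistributable,
        )
        persist("fv_correct", (corrected, exclusions))

        edible = stage_edible(bundle, corrected)
        persist("edible", (edible.supplies, edible.losses))

        national = stage_nutrients(
            bundle, edible.supplies, config.n_iter, config.seed, nutrients
        )
        persist("nutrients", (national,))

        fortified = stage_fortify(
            bundle, national, edible.supplies, config.target_year,
            config.apply_voluntary_fortification,
        )
        persist("fortify", (fortified,))

        group_foods, group_nutrients = stage_agesex(
            bundle, edible.supplies, national, config.n_iter, config.seed,
            config.target_year, nutrients,
        )
        persist("agesex", (group_foods, group_nutrients))
    except Exception as exc:
        done = stages[-1]["stage"] if stages else None
        failed = next(
            (s for s in STAGE_FILES if s not in {st["stage"] for st in stages}), "?"
        )
        raise RuntimeError(
            f"pipeline aborted in stage {failed!r} (last completed: {done!r}): {exc}"
        ) from exc
    finally:
        log.removeHandler(collector)

    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=config.seed,
        stages=stages,
        outputs=outputs,
        warnings=collector.messages,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
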