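"""Primary → retail → edible weight conversion and processed-food transforms.

Balance sheets report farm, carcass or landed weight, while nutrient
densities are quoted per 100 g of *edible* portion. Meat and seafood lose
mass at butchering/filleting (carcass→retail factor); every food then
loses its inedible discard (peels, bones, shells). Plant foods skip the
retail step — farm-to-retail losses are already inside the reported
supplies — but their basis still advances.

Two processed-food transforms change nutrient identity rather than mass
basis: a share of wheat, maize, millet and sorghum supply becomes refined
flour (a new food row, at the grain-to-flour extraction rate; rice is
excluded because it is already reported milled), and cheese composition
entries are folded back to whole-milk equivalent by the milkfat factor so
they can sit in the milk candidate pool.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Mapping

import pandas as pd

log = logging.getLogger("nutrisupply")

#: Grains subject to the refined-flour split. Rice is reported in milled
#: weight already and must never be split.
SPLITTABLE_GRAINS = ("wheat", "maize", "millet", "sorghum")


@dataclasses.dataclass(frozen=True)
class EdibleFactors:
    """Carcass→retail fraction (None for plant foods) and discard fraction."""

    food: str
    carcass_to_retail: float | None = None
    discard_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.carcass_to_retail is not None and not (0 < self.carcass_to_retail <= 1):
            raise ValueError(f"{self.food}: carcass_to_retail must be in (0, 1]")
        if not (0 <= self.discard_fraction < 1):
            raise ValueError(f"{self.food}: discard_fraction must be in [0, 1)")


@dataclasses.dataclass(frozen=True)
class GrainProcessing:
    """Refined-flour parameters for one grain in one region."""

    grain: str
    region: str
    processed_fraction: float  # share of supply that is milled to flour
    extraction_rate: float  # flour mass out per unit grain milled

    def __post_init__(self) -> None:
        if self.grain == "rice":
            raise ValueError("rice is reported in milled weight and is never split to flour")
        if not (0 <= self.processed_fraction <= 1):
            raise ValueError(f"{self.grain}/{self.region}: processed_fraction must be in [0, 1]")
        if not (0 < self.extraction_rate <= 1):
            raise ValueError(f"{self.grain}/{self.region}: extraction_rate must be in (0, 1]")


def to_retail(primary: float, carcass_to_retail: float | None) -> float:
    """Carcass/landed weight → retail weight. ``None`` factor = plant pass-through."""
    if primary < 0 or not math.isfinite(primary):
        raise ValueError(f"primary supply must be finite and >= 0, got {primary!r}")
    if carcass_to_retail is None:
        return primary
    if not (0 < carcass_to_retail <= 1):
        raise ValueError(f"carcass_to_retail must be in (0, 1], got {carcass_to_retail!r}")
    return primary * carcass_to_retail


def to_edible(retail: float, discard_fraction: float) -> float:
    """Retail weight → edible weight by subtracting the inedible discard share."""
    if retail < 0 or not math.isfinite(retail):
        raise ValueError(f"retail supply must be finite and >= 0, got {retail!r}")
    if not (0 <= discard_fraction < 1):
        raise ValueError(f"discard_fraction must be in [0, 1), got {discard_fraction!r}")
    return retail * (1.0 - discard_fraction)


def split_grain(grain_supply: float, gp: GrainProcessing) -> tuple[float, float]:
    """Split a grain supply into (refined flour, remaining whole grain).

    flour = supply × processed_fraction × extraction_rate;
    whole = supply × (1 − processed_fraction). The milling loss
    (1 − extraction_rate on the processed share) leaves the food supply.
    The whole-grain remainder keeps its whole-grain nutrient identity.
    """
    if grain_supply < 0 or not math.isfinite(grain_supply):
        raise ValueError(f"grain supply must be finite and >= 0, got {grain_supply!r}")
    flour = grain_supply * gp.processed_fraction * gp.extraction_rate
    whole = grain_supply * (1.0 - gp.processed_fraction)
    return flour, whole


def cheese_to_milk_equivalent(
    cheese_density: Mapping[str, float],
    milkfat_factor: float,
) -> dict[str, float]:
    """Fold a cheese composition entry back to whole-milk equivalent.

    Each nutrient density is divided by the milkfat conversion factor (kg
    of milk per kg of cheese), so the entry can join the milk candidate
    pool on a per-100-g-of-milk basis.
    """
    if not math.isfinite(milkfat_factor) or milkfat_factor <= 0:
        raise ValueError(f"milkfat factor must be > 0, got {milkfat_factor!r}")
    return {n: d / milkfat_factor for n, d in cheese_density.items()}


def normalize_to_milkfat(
    cheese_density: Mapping[str, float],
    target_fat_per_100g: float,
    fat_nutrient: str = "fat",
) -> dict[str, float]:
    """Scale a soft-cheese entry so its fat density matches local whole milk.

    Used for soft cheeses that are close to condensed milk (channa, khoa):
    all densities are multiplied by ``target_fat / cheese_fat``, making the
    fat content equal the configured whole-milk value.
    """
    if target_fat_per_100g <= 0:
        raise ValueError("target fat density must be > 0")
    cheese_fat = cheese_density.get(fat_nutrient, 0.0)
    if cheese_fat <= 0:
        raise ValueError(f"cheese entry has no positive {fat_nutrient!r} density to normalize by")
    scale = target_fat_per_100g / cheese_fat
    return {n: d * scale for n, d in cheese_density.items()}


@dataclasses.dataclass
class EdibleResult:
    """Edible-basis supply frame plus a mass-loss ledger per food row."""

    supplies: pd.DataFrame  # country, year, food, amount_g_day, basis=edible
    losses: pd.DataFrame  # country, year, food, primary_g_day, edible_g_day, loss_g_day


def edible_table(
    supplies: pd.DataFrame,
    factors: Mapping[str, EdibleFactors],
    grain_processing: Mapping[tuple[str, str], GrainProcessing] | None = None,
    country_region: Mapping[str, str] | None = None,
) -> EdibleResult:
    """Convert a primary-basis supply frame to edible basis, adding flour rows.

    ``supplies`` columns: country, year, food, amount_g_day, basis
    (=primary). Foods without an entry in ``factors`` pass through with no
    retail loss and no discard. The refined-flour split runs on the
    edible-basis grain supply (fortificants and composition matches apply
    at the flour stage); flour rows are named ``<grain>_flour``.
    """
    grain_processing = grain_processing or {}
    country_region = country_region or {}
    rows: list[tuple[str, int, str, float, str]] = []
    loss_rows: list[tuple[str, int, str, float, float, float]] = []
    for r in supplies.itertuples(index=False):
        if str(r.basis) != "primary":
            raise ValueError(f"edible_table expects primary basis, got {r.basis!r} for {r.food}")
        food = str(r.food)
        f = factors.get(food, EdibleFactors(food))
        retail = to_retail(float(r.amount_g_day), f.carcass_to_retail)
        edible = to_edible(retail, f.discard_fraction)
        country, year = str(r.country), int(r.year)
        region = country_region.get(country, "global")
        gp = grain_processing.get((food, region)) or grain_processing.get((food, "global"))
        if gp is not None:
            flour, whole = split_grain(edible, gp)
            rows.append((country, year, food, whole, "edible"))
            rows.append((country, year, f"{food}_flour", flour, "edible"))
            loss_rows.append(
                (country, year, food, float(r.amount_g_day), flour + whole,
                 float(r.amount_g_day) - flour - whole)
            )
        else:
            rows.append((country, year, food, edible, "edible"))
            loss_rows.append(
                (country, year, food, float(r.amount_g_day), edible,
                 float(r.amount_g_day) - edible)
            )
    cols = ["country", "year", "food", "amount_g_day", "basis"]
    loss_cols = ["country", "year", "food", "primary_g_day", "edible_g_day", "loss_g_day"]
    return EdibleResult(
        pd.DataFrame(rows, columns=cols),
        pd.DataFrame(loss_rows, columns=loss_cols),
    )
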