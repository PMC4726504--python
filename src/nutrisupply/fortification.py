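"""Fortification overlay on top of the Monte Carlo nutrient summaries.

Fortification guidelines state a range of nutrient mass added per kilogram
of a vehicle food (flour, oil, salt...). The overlay is deterministic: the
*lower* bound of the stated range is used — part of the added nutrient is
lost in processing, storage and transport, so the low end better reflects
what reaches the consumed product — and for cereal flours only the
industrially milled share of the supply is reachable by fortification
programs, so the addition is scaled by that fraction. The resulting
per-nutrient additions shift the unfortified median and both uncertainty
bounds equally.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Mapping

import pandas as pd

log = logging.getLogger("nutrisupply")


@dataclasses.dataclass(frozen=True)
class FortificationRule:
    """Nutrient added to one vehicle in one country, per kg of vehicle."""

    country: str
    vehicle: str
    nutrient: str
    amount_low: float  # nutrient units (matching the nutrient panel) per kg vehicle
    amount_high: float
    status: str  # "mandatory" or "voluntary"

    def __post_init__(self) -> None:
        if not (0 <= self.amount_low <= self.amount_high):
            raise ValueError(
                f"{self.country}/{self.vehicle}/{self.nutrient}: need 0 <= low <= high"
            )
        if self.status not in ("mandatory", "voluntary"):
            raise ValueError(f"unknown fortification status {self.status!r}")


def is_flour_vehicle(vehicle: str) -> bool:
    """Flour vehicles are the only ones gated by the industrial-milling share."""
    return vehicle.endswith("_flour") or vehicle == "flour"


def fortified_addition(
    vehicle: str,
    vehicle_supply_g_day: float,
    rule: FortificationRule,
    industrial_fraction: float = 1.0,
) -> float:
    """Daily nutrient addition from one rule applied to one vehicle supply.

    addition = supply (kg/day) × amount_low (per kg) × industrial fraction.
    Non-flour vehicles always use fraction 1 — the milling gate only
    applies to cereal flours.
    """
    if rule.vehicle != vehicle:
        raise ValueError(f"rule for vehicle {rule.vehicle!r} applied to {vehicle!r}")
    if vehicle_supply_g_day < 0:
        raise ValueError("vehicle supply must be >= 0")
    if not (0 <= industrial_fraction <= 1):
        raise ValueError(f"industrial fraction must be in [0, 1], got {industrial_fraction!r}")
    fraction = industrial_fraction if is_flour_vehicle(vehicle) else 1.0
    return (vehicle_supply_g_day / 1000.0) * rule.amount_low * fraction


def total_additions(
    supplies: Mapping[str, float],
    rules: Iterable[FortificationRule],
    industrial_fractions: Mapping[str, float] | None = None,
    include_voluntary: bool = True,
) -> dict[str, float]:
    """Sum rule additions for one country: nutrient → amount/person/day.

    ``supplies`` maps food → edible g/person/day for the target year;
    rules whose vehicle has no supply contribute nothing.
    ``industrial_fractions`` maps flour vehicles to their industrially
    milled share (default 1).
    """
    industrial_fractions = industrial_fractions or {}
    out: dict[str, float] = {}
    for rule in rules:
        if rule.status == "voluntary" and not include_voluntary:
            continue
        supply = supplies.get(rule.vehicle)
        if supply is None:
            continue
        frac = industrial_fractions.get(rule.vehicle, 1.0)
        add = fortified_addition(rule.vehicle, supply, rule, frac)
        out[rule.nutrient] = out.get(rule.nutrient, 0.0) + add
    return out


def apply_fortification(
    national: pd.DataFrame,
    supplies: pd.DataFrame,
    rules: Iterable[FortificationRule],
    industrial_fractions: Mapping[tuple[str, str], float] | None = None,
    target_year: int | None = None,
    include_voluntary: bool = True,
) -> pd.DataFrame:
    """Shift national nutrient summaries by the fortification additions.

    ``national``: the frame from ``national_nutrients`` (median/lower/upper
    per country-year-nutrient). ``supplies``: the edible supply frame used
    to look up vehicle supplies. The overlay applies only to
    ``target_year`` (the most recent year in ``national`` when None);
    other years pass through unchanged. ``industrial_fractions`` is keyed
    by (country, vehicle). The shift adds the same amount to median and
    both bounds, so fortified >= unfortified for every statistic.
    """
    industrial_fractions = industrial_fractions or {}
    rules = list(rules)
    if target_year is None:
        target_year = int(national["year"].max())
    out = national.copy()
    by_country_rules: dict[str, list[FortificationRule]] = {}
    for r in rules:
        by_country_rules.setdefault(r.country, []).append(r)
    year_supplies = supplies[supplies["year"] == target_year]
    for country, crules in by_country_rules.items():
        cs = year_supplies[year_supplies["country"] == country]
        supply_map = {str(r.food): float(r.amount_g_day) for r in cs.itertuples(index=False)}
        fracs = {
            r.vehicle: industrial_fractions.get((country, r.vehicle), 1.0) for r in crules
        }
        adds = total_additions(supply_map, crules, fracs, include_voluntary)
        for nutrient, delta in adds.items():
            mask = (
                (out["country"] == country)
                & (out["year"] == target_year)
                & (out["nutrient"] == nutrient)
            )
            out.loc[mask, ["median", "lower_95", "upper_95"]] += delta
    return out
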