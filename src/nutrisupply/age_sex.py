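"""Disaggregate national per-capita supplies into age-sex-group supplies.

National averages hide large differences between demographic groups. The
chain here: (1) normalize each national food supply to a 2,000 kcal
reference diet; (2) scale by the group's relative-intake ratio for the
food's dietary category (survey-derived ratios, population-weighted to 1
across adult groups); (3) allocate the national calorie supply to groups
in proportion to their energy requirements; (4) de-normalize each group's
adjusted supplies with its own calorie supply; and (5) rescale per food so
the population-weighted group supplies reproduce the national per-capita
supply exactly.

Foods without a matching intake category keep the average adjusted value
for every group ("uniform"); adult-only foods (alcohol, stimulants,
spices) are zeroed for under-20 groups; children and adolescents, for whom
no survey ratios exist, take the average value.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .nutrient_mc import (
    NUTRIENTS,
    CompositionEntry,
    MCSummary,
    candidate_matrix,
    draw_choices,
    iteration_totals,
    summarize,
)

log = logging.getLogger("nutrisupply")

REFERENCE_DIET_KCAL = 2000.0
ADULT_AGE = 20

#: GddMap special-handling values besides a plain category name.
UNIFORM = "uniform"
ADULT_ONLY = "adult_only"
FATTY_ACID_PREFIX = "fatty_acid_proxy:"


@dataclasses.dataclass(frozen=True)
class AgeSexGroup:
    """One sex × 5-year age bracket with population and energy requirement."""

    sex: str  # "female" | "male"
    age_low: int
    age_high: int | None  # None = open-ended top bracket
    population: float
    energy_requirement: float  # kcal/person/day

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.population < 0:
            raise ValueError("population must be >= 0")
        if self.energy_requirement <= 0:
            raise ValueError("energy_requirement must be > 0")

    @property
    def group_id(self) -> str:
        hi = "plus" if self.age_high is None else str(self.age_high)
        return f"{'F' if self.sex == 'female' else 'M'}{self.age_low}_{hi}"

    @property
    def is_adult(self) -> bool:
        return self.age_low >= ADULT_AGE


def energy_adjust(
    food_supply: float,
    national_energy: float,
    reference_kcal: float = REFERENCE_DIET_KCAL,
) -> float:
    """Normalize a per-capita food supply to the reference calorie diet.

    adjusted = supply × reference / national energy supply, so that a
    country supplying 3,000 kcal/day and 30 g/day of a food has a
    2,000-kcal-adjusted supply of 20 g/day.
    """
    if national_energy <= 0:
        raise ValueError(f"national energy supply must be > 0, got {national_energy!r}")
    if food_supply < 0:
        raise ValueError("food supply must be >= 0")
    return food_supply * reference_kcal / national_energy


def apply_group_ratio(
    adjusted_supply: float,
    mapping: str,
    ratio: float | None,
    is_adult: bool,
) -> float:
    """Group-specific calorie-adjusted supply from the national adjusted value.

    ``mapping`` is the food's GddMap entry: a category name or fatty-acid
    proxy (ratio applies when available), ``uniform`` (all groups take the
    average), or ``adult_only`` (zero for under-20 groups). Groups without
    a ratio — children and adolescents — take the average value.
    """
    if adjusted_supply < 0:
        raise ValueError("adjusted supply must be >= 0")
    if mapping == UNIFORM:
        return adjusted_supply
    if mapping == ADULT_ONLY:
        if not is_adult:
            return 0.0
        return adjusted_supply * ratio if ratio is not None else adjusted_supply
    # category or fatty-acid proxy: ratio multiplication, average fallback
    if ratio is None:
        return adjusted_supply
    if ratio <= 0:
        raise ValueError(f"intake ratio must be > 0, got {ratio!r}")
    return adjusted_supply * ratio


def group_energy_supply(
    national_energy: float,
    groups: Sequence[AgeSexGroup],
) -> dict[str, float]:
    """Allocate the national calorie supply to groups in proportion to needs.

    The population-weighted average requirement sets the surplus factor
    ``f = national / avg_requirement``; each group receives
    ``requirement × f``, so the population-weighted mean of group supplies
    equals the national supply exactly.
    """
    if national_energy <= 0:
        raise ValueError("national energy supply must be > 0")
    total_pop = sum(g.population for g in groups)
    if total_pop <= 0:
        raise ValueError("total population must be > 0")
    avg_req = sum(g.population * g.energy_requirement for g in groups) / total_pop
    factor = national_energy / avg_req
    return {g.group_id: g.energy_requirement * factor for g in groups}


def deadjust(
    group_adjusted: float,
    group_energy: float,
    reference_kcal: float = REFERENCE_DIET_KCAL,
) -> float:
    """Convert a calorie-adjusted supply back to absolute g/person/day."""
    if group_energy <= 0:
        raise ValueError("group energy supply must be > 0")
    if group_adjusted < 0:
        raise ValueError("adjusted supply must be >= 0")
    return group_adjusted * group_energy / reference_kcal


def enforce_population_consistency(
    group_supplies: pd.DataFrame,
    populations: Mapping[str, float],
    national_supply: Mapping[str, float],
) -> pd.DataFrame:
    """Rescale per food so population-weighted group supplies match national.

    ``group_supplies`` is foods × groups. The ratio+energy chain does not
    land exactly on the national per-capita supply when some groups take
    average values, so each food row is multiplied by
    ``national / weighted_mean`` as an explicit final constraint.
    """
    pops = np.array([float(populations[g]) for g in group_supplies.columns])
    total_pop = pops.sum()
    if total_pop <= 0:
        raise ValueError("total population must be > 0")
    out = group_supplies.copy().astype(float)
    for food in out.index:
        national = float(national_supply[food])
        weighted = float(out.loc[food].to_numpy() @ pops) / total_pop
        if national > 0 and weighted <= 0:
            raise ValueError(
                f"food {food!r}: all-zero group supplies with positive national supply"
            )
        out.loc[food] = 0.0 if national == 0 else out.loc[food] * (national / weighted)
    return out


def group_food_supplies(
    national_supplies: Mapping[str, float],
    national_energy: float,
    groups: Sequence[AgeSexGroup],
    gdd_map: Mapping[str, str],
    ratios: Mapping[tuple[str, str], float],
    reference_kcal: float = REFERENCE_DIET_KCAL,
) -> pd.DataFrame:
    """Full chain for one country-year: foods × groups, absolute g/person/day.

    ``gdd_map`` maps food → category / ``uniform`` / ``adult_only`` /
    ``fatty_acid_proxy:<which>``; ``ratios`` maps (category-or-proxy,
    group_id) → ratio for adult groups. The result satisfies the
    population-weighted consistency constraint per food.
    """
    energies = group_energy_supply(national_energy, groups)
    foods = sorted(national_supplies)
    data = np.zeros((len(foods), len(groups)))
    for i, food in enumerate(foods):
        if food not in gdd_map:
            raise KeyError(f"food {food!r} has no dietary-category mapping")
        mapping = gdd_map[food]
        key_cat = mapping[len(FATTY_ACID_PREFIX):] if mapping.startswith(FATTY_ACID_PREFIX) else mapping
        adjusted = energy_adjust(national_supplies[food], national_energy, reference_kcal)
        for j, g in enumerate(groups):
            ratio = ratios.get((key_cat, g.group_id)) if g.is_adult else None
            per_group = apply_group_ratio(adjusted, mapping, ratio, g.is_adult)
            data[i, j] = deadjust(per_group, energies[g.group_id], reference_kcal)
    frame = pd.DataFrame(data, index=foods, columns=[g.group_id for g in groups])
    populations = {g.group_id: g.population for g in groups}
    return enforce_population_consistency(frame, populations, dict(national_supplies))


def group_nutrients(
    group_food_supplies: pd.DataFrame,
    candidates: Mapping[str, Sequence[CompositionEntry]],
    n_iter: int,
    seed: int | np.random.Generator,
    nutrients: Sequence[str] = NUTRIENTS,
) -> dict[str, dict[str, MCSummary]]:
    """Monte Carlo nutrient summaries per group under *shared* candidate draws.

    All groups see the same per-iteration candidate choice for each food —
    the composition ambiguity is a property of the food, not of the group —
    so group totals stay comparable and weighted aggregates of iteration
    totals reproduce the national iteration totals.

    Returns group_id → nutrient → summary.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    foods = list(group_food_supplies.index)
    for food in foods:
        if food not in candidates or not candidates[food]:
            raise KeyError(f"no candidate composition entries for food {food!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    matrices = [candidate_matrix(candidates[f], nutrients, f) for f in foods]
    choices = draw_choices([m.shape[0] for m in matrices], n_iter, rng)
    supply_matrix = group_food_supplies.to_numpy(dtype=float)
    totals = iteration_totals(supply_matrix, matrices, choices)
    out: dict[str, dict[str, MCSummary]] = {}
    for j, group_id in enumerate(group_food_supplies.columns):
        out[group_id] = {
            n: summarize(totals[:, j, k], n, n_iter) for k, n in enumerate(nutrients)
        }
    return out
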