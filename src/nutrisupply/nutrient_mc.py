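"""Composition matching and Monte Carlo nutrient-supply estimation.

A balance-sheet food category ("Potatoes") rarely maps to a single
composition-table entry; several entries describe it equally well, with
different densities. Rather than picking one, the pipeline keeps every
equally good candidate and propagates the ambiguity: on each Monte Carlo
iteration one candidate per food is drawn uniformly and independently, the
per-food contributions (supply g/day × density per 100 g / 100) are
summed into a national total per nutrient, and the iteration totals are
summarised by their median and 2.5/97.5 percentiles — a 95% uncertainty
interval that reflects composition-table heterogeneity, not sampling
error in the supplies themselves.

Candidate lists come from a regional fallback chain: the regionally
appropriate table first, then (for sub-Saharan Africa) an older
continental table, then the US reference table, and finally a synthetic
candidate equal to the across-table average when no table lists the food.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("nutrisupply")

#: The default tracked-nutrient panel (23 nutrients) and units.
NUTRIENT_UNITS: dict[str, str] = {
    "calories": "kcal",
    "fat": "g",
    "protein": "g",
    "carbohydrates": "g",
    "dietary_fiber": "g",
    "vitamin_c": "mg",
    "thiamin": "mg",
    "riboflavin": "mg",
    "niacin": "mg",
    "vitamin_b6": "mg",
    "vitamin_a": "ug_rae",
    "folate": "ug",
    "calcium": "mg",
    "iron": "mg",
    "zinc": "mg",
    "potassium": "mg",
    "copper": "mg",
    "magnesium": "mg",
    "phosphorus": "mg",
    "selenium": "ug",
    "saturated_fa": "g",
    "monounsaturated_fa": "g",
    "polyunsaturated_fa": "g",
}

NUTRIENTS: tuple[str, ...] = tuple(NUTRIENT_UNITS)


@dataclasses.dataclass(frozen=True)
class CompositionEntry:
    """One composition-table entry: densities per 100 g edible portion."""

    table_id: str
    food: str
    densities: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.densities:
            raise ValueError(f"{self.table_id}/{self.food}: entry has no nutrients")
        for n, d in self.densities.items():
            if d < 0 or not np.isfinite(d):
                raise ValueError(f"{self.table_id}/{self.food}: bad density {d!r} for {n}")


@dataclasses.dataclass(frozen=True)
class MCSummary:
    """Median and 95% uncertainty interval of one nutrient's daily total."""

    nutrient: str
    median: float
    lower_95: float
    upper_95: float
    n_iterations: int

    def __post_init__(self) -> None:
        if not (self.lower_95 <= self.median <= self.upper_95):
            raise ValueError(
                f"{self.nutrient}: summary out of order "
                f"({self.lower_95}, {self.median}, {self.upper_95})"
            )

    def shifted(self, delta: float) -> "MCSummary":
        """Summary with a deterministic amount added to all three statistics."""
        return MCSummary(
            self.nutrient, self.median + delta, self.lower_95 + delta,
            self.upper_95 + delta, self.n_iterations,
        )


def composition_index(df: pd.DataFrame) -> dict[str, dict[str, list[CompositionEntry]]]:
    """Index a long composition frame as table_id → food → entries.

    Rows sharing (table_id, food, unit-consistent nutrient set) are one
    entry when they share an ``entry`` column value; without an ``entry``
    column each (table_id, food) pair is a single entry.
    """
    key_cols = ["table_id", "food"]
    if "entry" in df.columns:
        key_cols.append("entry")
    out: dict[str, dict[str, list[CompositionEntry]]] = {}
    for key, grp in df.groupby(key_cols, sort=True):
        table_id, food = str(key[0]), str(key[1])
        densities = {
            str(r.nutrient): float(r.density_per_100g) for r in grp.itertuples(index=False)
        }
        out.setdefault(table_id, {}).setdefault(food, []).append(
            CompositionEntry(table_id, food, densities)
        )
    return out


def resolve_candidates(
    food: str,
    country: str,
    tables: Mapping[str, Mapping[str, Sequence[CompositionEntry]]],
    region_map: Mapping[str, Sequence[str]],
) -> list[CompositionEntry]:
    """Candidate entries for a food in a country via the regional fallback chain.

    The country's chain (e.g. ``[west_africa, fao_africa, usda]``) is
    walked in order and the first table listing the food contributes *all*
    of its matching entries. If no chain table lists it, a single
    synthetic candidate is built as the per-nutrient mean over the
    per-table means of every table (in ``tables``) that lists the food.
    """
    if country not in region_map:
        raise KeyError(f"no composition-table chain for country {country!r}")
    for table_id in region_map[country]:
        table = tables.get(table_id, {})
        if food in table and table[food]:
            return list(table[food])
    # global-average fallback over all tables that know the food
    per_table_means: list[dict[str, float]] = []
    for table in tables.values():
        entries = table.get(food)
        if entries:
            nutrients = sorted({n for e in entries for n in e.densities})
            per_table_means.append(
                {
                    n: float(np.mean([e.densities[n] for e in entries if n in e.densities]))
                    for n in nutrients
                }
            )
    if not per_table_means:
        raise KeyError(f"food {food!r} absent from every composition table")
    nutrients = sorted({n for m in per_table_means for n in m})
    avg = {
        n: float(np.mean([m[n] for m in per_table_means if n in m])) for n in nutrients
    }
    log.info("food %s matched by global table average (%d tables)", food, len(per_table_means))
    return [CompositionEntry("__global_average__", food, avg)]


def candidates_for(
    food: str,
    country: str,
    tables: Mapping[str, Mapping[str, Sequence[CompositionEntry]]],
    region_map: Mapping[str, Sequence[str]],
    pool_fallback: Mapping[str, Sequence[str]] | None = None,
) -> list[CompositionEntry]:
    """:func:`resolve_candidates`, with a pooled fallback for synthetic foods.

    ``pool_fallback`` maps a food with no composition entry of its own
    (e.g. a retained nes residual) to member foods whose candidate lists
    are pooled for it — the group-average candidate set.
    """
    try:
        return resolve_candidates(food, country, tables, region_map)
    except KeyError:
        if pool_fallback and food in pool_fallback:
            pooled: list[CompositionEntry] = []
            for member in pool_fallback[food]:
                try:
                    pooled.extend(resolve_candidates(member, country, tables, region_map))
                except KeyError:
                    continue
            if pooled:
                log.info("food %s matched by pooled group candidates (%d)", food, len(pooled))
                return pooled
        raise


def country_rng(seed: int, country: str) -> np.random.Generator:
    """Deterministic per-country substream of the master seed.

    The country name is hashed so results do not depend on the order in
    which countries are processed.
    """
    digest = hashlib.sha256(country.encode("utf-8")).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), sub]))


def candidate_matrix(
    entries: Sequence[CompositionEntry],
    nutrients: Sequence[str],
    food: str = "?",
) -> np.ndarray:
    """(n_candidates × n_nutrients) density array with missing-value fill.

    A nutrient missing from one candidate is filled with the candidate-pool
    mean for that nutrient (logged); a nutrient absent from every candidate
    contributes 0 (logged).
    """
    if not entries:
        raise ValueError(f"empty candidate list for {food}")
    mat = np.full((len(entries), len(nutrients)), np.nan)
    for i, e in enumerate(entries):
        for j, n in enumerate(nutrients):
            if n in e.densities:
                mat[i, j] = e.densities[n]
    if np.isnan(mat).any():
        all_missing = np.isnan(mat).all(axis=0)
        col_mean = np.zeros(mat.shape[1])
        if (~all_missing).any():
            col_mean[~all_missing] = np.nanmean(mat[:, ~all_missing], axis=0)
        if all_missing.any():
            missing_names = [n for n, m in zip(nutrients, all_missing) if m]
            log.info("food %s: no candidate reports %s; contributes 0", food, missing_names)
            col_mean = np.where(all_missing, 0.0, col_mean)
        holes = np.isnan(mat)
        if (holes & ~all_missing[None, :]).any():
            log.info("food %s: missing densities filled with candidate-pool mean", food)
        mat = np.where(holes, col_mean[None, :], mat)
    if not np.isfinite(mat).all():
        raise ValueError(f"non-finite density for food {food}")
    return mat


def draw_choices(
    candidate_counts: Sequence[int],
    n_iter: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Per-food uniform candidate indices, independent across foods and iterations."""
    return [rng.integers(0, k, size=n_iter) for k in candidate_counts]


def iteration_totals(
    supply_matrix: np.ndarray,
    matrices: Sequence[np.ndarray],
    choices: Sequence[np.ndarray],
) -> np.ndarray:
    """Totals per (iteration, column, nutrient) for shared candidate draws.

    ``supply_matrix`` is (n_foods × n_columns) in g/person/day — columns
    are e.g. one national population or many age-sex groups sharing the
    same draws. Returns (n_iter × n_columns × n_nutrients).
    """
    n_iter = len(choices[0]) if choices else 0
    n_cols = supply_matrix.shape[1]
    n_nutr = matrices[0].shape[1] if matrices else 0
    totals = np.zeros((n_iter, n_cols, n_nutr))
    for f in range(supply_matrix.shape[0]):
        dens = matrices[f][choices[f], :]  # (n_iter × n_nutrients)
        totals += dens[:, None, :] * (supply_matrix[f, :][None, :, None] / 100.0)
    return totals


def summarize(totals_1d: np.ndarray, nutrient: str, n_iter: int) -> MCSummary:
    """Median and 2.5/97.5 percentiles (linear interpolation, "type 7")."""
    lo, med, hi = np.percentile(totals_1d, [2.5, 50.0, 97.5])
    return MCSummary(nutrient, float(med), float(lo), float(hi), n_iter)


def mc_nutrient_supply(
    supplies: Mapping[str, float],
    candidates: Mapping[str, Sequence[CompositionEntry]],
    n_iter: int,
    seed: int | np.random.Generator,
    nutrients: Sequence[str] = NUTRIENTS,
) -> dict[str, MCSummary]:
    """Monte Carlo per-nutrient supply summaries for one population.

    ``supplies`` maps food → edible g/person/day; ``candidates`` maps each
    food to its non-empty candidate entry list. One candidate per food is
    drawn uniformly on each of ``n_iter`` iterations; totals are
    summarised by median and 95% uncertainty interval. Identical seed and
    inputs reproduce identical summaries bit-for-bit.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    foods = sorted(supplies)
    for food in foods:
        if food not in candidates or not candidates[food]:
            raise KeyError(f"no candidate composition entries for food {food!r}")
        if supplies[food] < 0 or not np.isfinite(supplies[food]):
            raise ValueError(f"bad supply for {food!r}: {supplies[food]!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    matrices = [candidate_matrix(candidates[f], nutrients, f) for f in foods]
    choices = draw_choices([m.shape[0] for m in matrices], n_iter, rng)
    supply_matrix = np.array([[supplies[f]] for f in foods])  # (n_foods × 1)
    totals = iteration_totals(supply_matrix, matrices, choices)[:, 0, :]
    return {
        n: summarize(totals[:, j], n, n_iter) for j, n in enumerate(nutrients)
    }


def national_nutrients(
    supplies: pd.DataFrame,
    tables: Mapping[str, Mapping[str, Sequence[CompositionEntry]]],
    region_map: Mapping[str, Sequence[str]],
    n_iter: int,
    seed: int,
    nutrients: Sequence[str] = NUTRIENTS,
    pool_fallback: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Run the Monte Carlo per country-year over an edible supply frame.

    Returns a long frame: country, year, nutrient, unit, median,
    lower_95, upper_95. Country substreams are derived from the master
    seed by hashing the country name, so country order cannot change
    results.
    """
    rows = []
    for (country, year), grp in supplies.groupby(["country", "year"], sort=True):
        food_supply = {str(r.food): float(r.amount_g_day) for r in grp.itertuples(index=False)}
        cand = {
            f: candidates_for(f, str(country), tables, region_map, pool_fallback)
            for f in food_supply
        }
        rng = country_rng(seed, str(country))
        summaries = mc_nutrient_supply(food_supply, cand, n_iter, rng, nutrients)
        for n in nutrients:
            s = summaries[n]
            rows.append(
                (country, year, n, NUTRIENT_UNITS.get(n, ""), s.median, s.lower_95, s.upper_95)
            )
    return pd.DataFrame(
        rows,
        columns=["country", "year", "nutrient", "unit", "median", "lower_95", "upper_95"],
    )
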