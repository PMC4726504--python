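"""Expand broad balance-sheet categories into individual foods.

National balance sheets report broad residual categories ("Fruits, other",
"Cereals, other") that pool many foods with very different nutrient
profiles. This module replicates the balance-sheet method at the level of
the constituent foods: each child's domestic supply is computed from its
own production and trade (processed forms folded back to primary
equivalent), the parent's food/domestic-supply ratio is applied to every
child, and agreement between the summed children and the parent total is
scored with an r² statistic about the 1:1 line.

Offals are a known failure mode of the trade-based route, so they are
re-estimated from meat carcass weight via live-weight conversion factors.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("nutrisupply")


@dataclasses.dataclass(frozen=True)
class CategoryMap:
    """One broad parent category and its constituent foods.

    ``primary_equivalent_factors`` maps a processed-form commodity name
    (e.g. dried fruit) to ``(child food, factor)``: processed tonnage times
    the factor gives primary-equivalent tonnage credited to that child.
    ``disaggregate=False`` passes the parent through unchanged (used for
    categories whose members are nutritionally homogeneous).
    """

    parent: str
    children: tuple[str, ...]
    primary_equivalent_factors: Mapping[str, tuple[str, float]] = dataclasses.field(
        default_factory=dict
    )
    disaggregate: bool = True

    def __post_init__(self) -> None:
        for form, (child, factor) in self.primary_equivalent_factors.items():
            if child not in self.children:
                raise ValueError(f"{self.parent}: processed form {form} maps to unknown child {child}")
            if not (factor > 0) or not math.isfinite(factor):
                raise ValueError(f"{self.parent}: factor for {form} must be finite and > 0")


@dataclasses.dataclass(frozen=True)
class OffalFactors:
    """Carcass→live and live→offal conversion factors for one animal type."""

    animal_type: str
    carcass_to_live: float
    live_to_offal: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.carcass_to_live) and self.carcass_to_live > 0):
            raise ValueError(f"{self.animal_type}: carcass_to_live must be finite and > 0")
        if not (0 < self.live_to_offal < 1):
            raise ValueError(f"{self.animal_type}: live_to_offal must be in (0, 1)")


def _check_nonneg_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")


def domestic_supply(production: float, imports: float, exports: float) -> float:
    """Domestic supply = production + imports − exports, floored at zero.

    Re-exporting entrepôts can show exports exceeding production plus
    imports; the negative balance is clamped to zero (and logged) because
    every downstream step is multiplicative and requires non-negative mass.
    """
    _check_nonneg_finite("production", production)
    _check_nonneg_finite("imports", imports)
    _check_nonneg_finite("exports", exports)
    net = production + imports - exports
    if net < 0:
        log.warning(
            "negative domestic supply clamped to 0 (production=%s imports=%s exports=%s)",
            production, imports, exports,
        )
        return 0.0
    return net


def to_primary_equivalent(processed_amount: float, factor: float) -> float:
    """Convert a processed-form tonnage back to its primary commodity weight."""
    _check_nonneg_finite("processed_amount", processed_amount)
    if not math.isfinite(factor) or factor <= 0:
        raise ValueError(f"primary-equivalent factor must be > 0, got {factor!r}")
    return processed_amount * factor


def apply_food_ratio(
    child_domestic: Mapping[str, float],
    parent_domestic: float,
    parent_food: float,
) -> dict[str, float]:
    """Allocate food supply to children using the parent's food ratio.

    Stock changes and non-food uses are only known at the parent level, so
    each child inherits the parent's food/domestic-supply ratio:
    ``child_food = child_domestic × parent_food / parent_domestic``.
    """
    _check_nonneg_finite("parent_food", parent_food)
    if parent_domestic <= 0:
        if parent_food > 0:
            raise ValueError(
                "parent domestic supply is 0 with positive food supply; ratio undefined"
            )
        return {child: 0.0 for child in child_domestic}
    ratio = parent_food / parent_domestic
    out = {}
    for child, dom in child_domestic.items():
        _check_nonneg_finite(f"child_domestic[{child}]", dom)
        out[child] = dom * ratio
    return out


def offal_supply(
    meat_carcass: Mapping[str, float],
    factors: Mapping[str, OffalFactors],
) -> float:
    """Total offal tonnage re-derived from meat carcass weights.

    Per animal type: offal = carcass × carcass_to_live × live_to_offal.
    """
    total = 0.0
    for animal, carcass in meat_carcass.items():
        _check_nonneg_finite(f"carcass[{animal}]", carcass)
        if animal not in factors:
            raise KeyError(f"no offal factors for animal type {animal!r}")
        f = factors[animal]
        total += carcass * f.carcass_to_live * f.live_to_offal
    return total


def one_to_one_r2(model: Sequence[float], reference: Sequence[float]) -> float:
    """r² of ``model`` against ``reference`` about the 1:1 line.

    This is a residual statistic, not a squared correlation:
    ``1 − Σ(ref−model)² / Σ(ref−mean(ref))²``. It is 1 for exact
    agreement and unbounded below (a badly offset model scores < 0);
    negative values are reported as computed.
    """
    m = np.asarray(model, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 1 or m.size < 2:
        raise ValueError("model and reference must be equal-length 1-d vectors of length >= 2")
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite value in r² inputs")
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("reference vector is constant; r² denominator undefined")
    ss_res = float(np.sum((r - m) ** 2))
    return 1.0 - ss_res / ss_tot


def child_domestic_supplies(
    flows: pd.DataFrame,
    cmap: CategoryMap,
    country: str,
    year: int,
) -> dict[str, float]:
    """Domestic supply per child for one country-year, tonnes.

    ``flows`` is the wide frame from :func:`nutrisupply.fbs_io.flows_to_frame`.
    Processed-form commodities are converted to primary equivalent and
    credited to their child before the balance is taken. Child-level stock
    or non-food-use data in the input is ignored (with a logged note):
    those elements are only handled through the parent ratio.
    """
    sub = flows[(flows["country"] == country) & (flows["year"] == year)]
    by_commodity = sub.set_index("commodity")
    out: dict[str, float] = {}
    for child in cmap.children:
        if child in by_commodity.index:
            row = by_commodity.loc[child]
            if float(row.get("stock_change", 0.0)) != 0.0:
                log.info(
                    "child-level stock_change for %s/%s/%s ignored (parent ratio governs)",
                    country, year, child,
                )
            out[child] = domestic_supply(
                float(row["production"]), float(row["imports"]), float(row["exports"])
            )
        else:
            out[child] = 0.0
    for form, (child, factor) in cmap.primary_equivalent_factors.items():
        if form in by_commodity.index:
            row = by_commodity.loc[form]
            processed_net = domestic_supply(
                float(row["production"]), float(row["imports"]), float(row["exports"])
            )
            out[child] += to_primary_equivalent(processed_net, factor)
    return out


@dataclasses.dataclass
class DisaggregationResult:
    """Long food-supply frame (tonnes, primary basis) plus the r² report."""

    supplies: pd.DataFrame  # columns: country, year, food, amount_tonnes
    report: pd.DataFrame  # columns: parent_category, r2, n_points


def disaggregate_table(
    child_flows: pd.DataFrame,
    parent_flows: pd.DataFrame,
    category_maps: Sequence[CategoryMap],
    offal_factors: Mapping[str, OffalFactors] | None = None,
    offal_parent: str = "offals",
    meat_parent: str = "meat",
) -> DisaggregationResult:
    """Run the disaggregation over every country-year and category.

    ``parent_flows`` holds the broad-category balances (including the
    ``food`` element); ``child_flows`` holds production/trade rows for the
    constituent foods and their processed forms. Parents whose map says
    ``disaggregate=False`` pass through as single foods. If
    ``offal_factors`` is given, the parent named ``offal_parent`` is
    re-estimated from the carcass domestic supplies of the children of
    ``meat_parent`` instead of from its own trade data.
    """
    rows: list[tuple[str, int, str, float]] = []
    report_rows: list[tuple[str, float, int]] = []
    keys = parent_flows[["country", "year"]].drop_duplicates().itertuples(index=False)
    keys = [(str(k.country), int(k.year)) for k in keys]
    parent_ix = parent_flows.set_index(["country", "year", "commodity"])

    meat_map = next((c for c in category_maps if c.parent == meat_parent), None)

    for cmap in category_maps:
        model_totals: list[float] = []
        ref_totals: list[float] = []
        for country, year in keys:
            try:
                prow = parent_ix.loc[(country, year, cmap.parent)]
            except KeyError:
                continue
            parent_dom = domestic_supply(
                float(prow["production"]), float(prow["imports"]), float(prow["exports"])
            )
            parent_food = float(prow["food"])
            if not cmap.disaggregate:
                rows.append((country, year, cmap.parent, parent_food))
                continue
            if cmap.parent == offal_parent and offal_factors is not None and meat_map is not None:
                carcass = child_domestic_supplies(child_flows, meat_map, country, year)
                dom_total = offal_supply(carcass, offal_factors)
                child_dom = {offal_parent: dom_total}
            else:
                child_dom = child_domestic_supplies(child_flows, cmap, country, year)
            child_food = apply_food_ratio(child_dom, parent_dom, parent_food)
            rows.extend((country, year, food, amt) for food, amt in child_food.items())
            model_totals.append(sum(child_dom.values()))
            ref_totals.append(parent_dom)
        if cmap.disaggregate and len(ref_totals) >= 2 and len(set(ref_totals)) > 1:
            r2 = one_to_one_r2(model_totals, ref_totals)
            report_rows.append((cmap.parent, r2, len(ref_totals)))
    supplies = pd.DataFrame(rows, columns=["country", "year", "food", "amount_tonnes"])
    report = pd.DataFrame(report_rows, columns=["parent_category", "r2", "n_points"])
    return DisaggregationResult(supplies, report)


def to_per_capita(
    supplies: pd.DataFrame,
    population: Mapping[str, float],
    days_per_year: float = 365.25,
) -> pd.DataFrame:
    """Convert tonnes/year food supplies to g/person/day.

    ``population`` maps country → persons. 1 tonne/year = 1e6 g/year.
    """
    out = supplies.copy()
    pop = out["country"].map(lambda c: float(population[c]))
    out["amount_g_day"] = out["amount_tonnes"] * 1e6 / (pop * days_per_year)
    out["basis"] = "primary"
    return out[["country", "year", "food", "amount_g_day", "basis"]]
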