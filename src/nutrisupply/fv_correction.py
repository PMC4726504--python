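"""Resolve "not elsewhere specified" fruit and vegetable supplies.

Sparse reporters often park most of their fruit or vegetable supply in a
residual "nes" category, which is useless for nutrient estimation because
densities vary widely within the group. The data-quality flag
disambiguates the two ways nes arises: genuinely consumed but unlisted
foods carry an *official* flag and are retained as their own category,
while balancing residuals carry *estimated*/*imputed* flags and are
redistributed over the named foods — by agricultural-census production
shares where a census exists, otherwise proportionally to the supplies
already estimated from production and trade. Countries that name five or
fewer categories in a group are excluded outright: too sparse to trust.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Mapping

from .fbs_io import DataFlag

log = logging.getLogger("nutrisupply")

SHARE_TOLERANCE = 1e-9


@dataclasses.dataclass(frozen=True)
class NesAssessment:
    """How much of a country's group supply hides in nes, and its provenance."""

    country: str
    food_group: str
    nes_share: float  # nes supply / group domestic supply, in [0, 1]
    dominant_flag: DataFlag | None  # flag carrying the largest nes amount
    n_reported_categories: int  # non-nes foods with positive supply


@dataclasses.dataclass(frozen=True)
class NesClassification:
    """Split of a group's nes supply by the retain/redistribute rule."""

    retained_official: float
    retained_unofficial: float
    redistributable: float

    @property
    def retained(self) -> float:
        return self.retained_official + self.retained_unofficial


def classify_nes(
    records: Iterable[tuple[float, DataFlag]],
    treat_unofficial_as_redistributable: bool = False,
) -> NesClassification:
    """Partition flagged nes amounts into retained and redistributable mass.

    Official nes is a real, distinct food category and is kept as-is.
    Estimated and imputed nes are balancing artifacts and join the
    redistributable pool. Unofficial nes is retained by default (with a
    warning), since its provenance is ambiguous; a switch lets it join the
    pool instead.
    """
    official = unofficial = redistributable = 0.0
    for amount, flag in records:
        if amount < 0:
            raise ValueError(f"nes amount must be >= 0, got {amount}")
        if flag is DataFlag.OFFICIAL:
            official += amount
        elif flag is DataFlag.UNOFFICIAL:
            if treat_unofficial_as_redistributable:
                redistributable += amount
            else:
                if amount > 0:
                    log.warning("unofficial nes supply of %s retained, not redistributed", amount)
                unofficial += amount
        else:  # estimated or imputed
            redistributable += amount
    return NesClassification(official, unofficial, redistributable)


def redistribute_census(
    nes_plus_reported_total: float,
    shares: Mapping[str, float],
) -> dict[str, float]:
    """Re-split a group total by census production shares.

    Replaces the within-group split entirely: the whole group total
    (named foods plus redistributable nes) is reallocated. Shares must sum
    to 1 within 1e-9; the last food absorbs the rounding residual so the
    outputs sum to the total exactly.
    """
    if nes_plus_reported_total < 0:
        raise ValueError("total must be >= 0")
    if not shares:
        raise ValueError("census shares are empty")
    ssum = 0.0
    for food, s in shares.items():
        if s < 0:
            raise ValueError(f"negative census share for {food}")
        ssum += s
    if abs(ssum - 1.0) > SHARE_TOLERANCE:
        raise ValueError(f"census shares sum to {ssum!r}, not 1")
    foods = list(shares)
    out = {f: nes_plus_reported_total * shares[f] for f in foods}
    out[foods[-1]] += nes_plus_reported_total - sum(out.values())
    return out


def redistribute_proportional(
    nes_amount: float,
    existing: Mapping[str, float],
) -> dict[str, float]:
    """Spread a redistributable nes amount over the named foods, pro rata.

    Each food gains ``nes × existing / Σ existing``; group mass is
    conserved. A group with no named supply cannot absorb nes mass — the
    exclusion rule should have removed such a country first.
    """
    if nes_amount < 0:
        raise ValueError("nes_amount must be >= 0")
    total = 0.0
    for food, amt in existing.items():
        if amt < 0:
            raise ValueError(f"negative existing supply for {food}")
        total += amt
    if nes_amount == 0:
        return dict(existing)
    if total <= 0:
        raise ValueError(
            "cannot redistribute nes over an all-zero group; exclusion rule should apply"
        )
    return {f: amt + nes_amount * amt / total for f, amt in existing.items()}


def exclusion_rule(n_reported_categories: int, threshold: int = 5) -> str:
    """``"exclude"`` when a country names ``threshold`` or fewer categories.

    The default of five is the conventional sparsity cutoff; it is
    deliberately configurable since it is a judgment call, not a derived
    quantity.
    """
    if n_reported_categories < 0:
        raise ValueError("n_reported_categories must be >= 0")
    return "exclude" if n_reported_categories <= threshold else "retain"


@dataclasses.dataclass
class GroupCorrection:
    """Outcome of correcting one country's fruit or vegetable group."""

    assessment: NesAssessment
    decision: str  # "retain" or "exclude"
    corrected: dict[str, float]  # food → amount; empty when excluded
    retained_nes: float  # official (+unofficial) nes kept as its own category


def correct_group(
    country: str,
    food_group: str,
    supplies: Mapping[str, float],
    nes_flags: Mapping[str, DataFlag],
    census_shares: Mapping[str, float] | None = None,
    threshold: int = 5,
    treat_unofficial_as_redistributable: bool = False,
    nes_label: str = "nes",
) -> GroupCorrection:
    """Apply the full nes workflow to one country-group.

    ``supplies`` maps every food in the group (nes categories included) to
    its amount; ``nes_flags`` gives the flag for each nes food (a food is
    treated as nes iff it appears here). When ``census_shares`` is given
    the whole group (named + redistributable nes) is re-split by the
    census; otherwise redistributable nes is spread proportionally.
    Retained nes mass is reported under ``<group>_<nes_label>_retained``.
    """
    nes_items = [(supplies.get(f, 0.0), flag) for f, flag in nes_flags.items()]
    named = {f: a for f, a in supplies.items() if f not in nes_flags}
    cls = classify_nes(nes_items, treat_unofficial_as_redistributable)
    group_total = sum(supplies.values())
    nes_total = sum(a for a, _ in nes_items)
    nes_share = nes_total / group_total if group_total > 0 else 0.0
    dominant = None
    if nes_items and nes_total > 0:
        by_flag: dict[DataFlag, float] = {}
        for a, fl in nes_items:
            by_flag[fl] = by_flag.get(fl, 0.0) + a
        dominant = max(by_flag, key=lambda k: by_flag[k])
    n_reported = sum(1 for a in named.values() if a > 0)
    assessment = NesAssessment(country, food_group, nes_share, dominant, n_reported)

    decision = exclusion_rule(n_reported, threshold)
    if decision == "exclude":
        log.warning(
            "%s/%s excluded: only %d reported categories (threshold %d)",
            country, food_group, n_reported, threshold,
        )
        return GroupCorrection(assessment, decision, {}, 0.0)

    if census_shares is not None:
        pool = sum(named.values()) + cls.redistributable
        corrected = redistribute_census(pool, census_shares)
    elif cls.redistributable > 0:
        corrected = redistribute_proportional(cls.redistributable, named)
    else:
        corrected = dict(named)
    return GroupCorrection(assessment, decision, corrected, cls.retained)
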