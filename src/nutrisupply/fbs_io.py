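"""Tabular I/O, data-quality flags and pipeline configuration.

Every table the pipeline reads or writes goes through this module. The
dialect is deliberately plain: UTF-8, comma-separated, one header row,
long format (one row per country-year-commodity-element), matching the
shape of FAOSTAT bulk exports so that real commodity-balance data can be
adapted with a column rename and a flag mapping.

Internal units are fixed: commodity flows are tonnes per year, per-capita
supplies are grams per person per day. The flow→supply conversion uses an
explicit population table and a 365.25-day year.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger("nutrisupply")


class ParseError(ValueError):
    """A table violated the documented dialect."""


class DataFlag(str, enum.Enum):
    """Provenance tag attached to each reported quantity.

    Commodity statistics come with a quality tag: reported by the country
    (*official*), reported by a non-governmental source (*unofficial*),
    estimated by the compiling agency (*estimated*), or carried forward
    from earlier estimates (*imputed*). The nes-correction stage branches
    on this distinction.
    """

    OFFICIAL = "official"
    UNOFFICIAL = "unofficial"
    ESTIMATED = "estimated"
    IMPUTED = "imputed"


#: Default mapping from raw flag characters to the four internal codes.
#: FAOSTAT has used blank for official, ``*`` for unofficial, ``E`` for
#: agency estimates and ``I`` for imputations; other eras differ, so the
#: mapping is configuration, not code.
DEFAULT_FLAG_MAP: dict[str, DataFlag] = {
    "": DataFlag.OFFICIAL,
    "*": DataFlag.UNOFFICIAL,
    "E": DataFlag.ESTIMATED,
    "I": DataFlag.IMPUTED,
}

#: The ten balance elements of a commodity flow row. ``stock_change`` is
#: the only element allowed to be negative (stock draw-down).
FLOW_ELEMENTS: tuple[str, ...] = (
    "production",
    "imports",
    "exports",
    "feed",
    "seed",
    "processing",
    "waste",
    "other_uses",
    "stock_change",
    "food",
)


class Basis(str, enum.Enum):
    """Weight basis of a per-capita food supply.

    Supplies start as *primary* weight (farm/carcass/landed), become
    *retail* after butchering-type losses, and *edible* after removing
    inedible discard. Transitions only ever advance primary→retail→edible.
    """

    PRIMARY = "primary"
    RETAIL = "retail"
    EDIBLE = "edible"


_BASIS_ORDER = {Basis.PRIMARY: 0, Basis.RETAIL: 1, Basis.EDIBLE: 2}


def advance_basis(current: Basis, target: Basis) -> Basis:
    """Validate a basis transition; only forward moves are legal."""
    if _BASIS_ORDER[target] < _BASIS_ORDER[current]:
        raise ValueError(f"illegal basis transition {current.value}->{target.value}")
    return target


@dataclasses.dataclass
class CommodityFlowRecord:
    """One country-year-commodity row of the balance, in tonnes/year."""

    country: str
    year: int
    commodity: str
    production: float = 0.0
    imports: float = 0.0
    exports: float = 0.0
    feed: float = 0.0
    seed: float = 0.0
    processing: float = 0.0
    waste: float = 0.0
    other_uses: float = 0.0
    stock_change: float = 0.0
    food: float = 0.0
    flags: dict[str, DataFlag] = dataclasses.field(default_factory=dict)

    def get(self, element: str) -> float:
        if element not in FLOW_ELEMENTS:
            raise KeyError(element)
        return getattr(self, element)


@dataclasses.dataclass
class FoodSupply:
    """Per-capita supply of one food in one country-year (g/person/day)."""

    country: str
    year: int
    food: str
    amount: float
    basis: Basis = Basis.PRIMARY

    def __post_init__(self) -> None:
        if not math.isfinite(self.amount) or self.amount < 0:
            raise ValueError(
                f"supply amount must be finite and >= 0, got {self.amount!r} "
                f"for {self.country}/{self.year}/{self.food}"
            )


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")


def read_flow_table(
    path: str | Path,
    flag_map: Mapping[str, DataFlag] | None = None,
) -> list[CommodityFlowRecord]:
    """Read a long-format flow table into one record per country-year-commodity.

    Columns: ``country,year,commodity,element,value,flag``. Each element of
    the balance is its own row and carries its own flag. Elements absent
    for a commodity default to 0 (flag official, vacuously).

    Raises
    ------
    ParseError
        Missing column, unknown element, unmapped flag code, non-finite
        value, duplicate element for one key, or a negative value in any
        element other than ``stock_change``.
    """
    path = Path(path)
    fmap = dict(DEFAULT_FLAG_MAP if flag_map is None else flag_map)
    df = pd.read_csv(path, dtype={"flag": str}, keep_default_na=False, na_values=[])
    _require_columns(df, ("country", "year", "commodity", "element", "value", "flag"), path)

    records: dict[tuple[str, int, str], CommodityFlowRecord] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        element = str(row.element)
        if element not in FLOW_ELEMENTS:
            raise ParseError(f"{path} row {i}: unknown element {element!r}")
        raw_flag = str(row.flag)
        if raw_flag not in fmap:
            raise ParseError(f"{path} row {i}: unmapped flag code {raw_flag!r}")
        try:
            value = float(row.value)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path} row {i}: non-numeric value {row.value!r}") from exc
        if not math.isfinite(value):
            raise ParseError(f"{path} row {i}: non-finite value in {element}")
        if value < 0 and element != "stock_change":
            raise ParseError(
                f"{path} row {i}: negative {element} ({value}) for "
                f"{row.country}/{row.year}/{row.commodity}"
            )
        key = (str(row.country), int(row.year), str(row.commodity))
        rec = records.get(key)
        if rec is None:
            rec = records[key] = CommodityFlowRecord(*key)
        if element in rec.flags:
            raise ParseError(f"{path} row {i}: duplicate element {element} for {key}")
        setattr(rec, element, value)
        rec.flags[element] = fmap[raw_flag]
    return list(records.values())


def write_flow_table(
    records: Iterable[CommodityFlowRecord],
    path: str | Path,
    flag_map: Mapping[str, DataFlag] | None = None,
) -> None:
    """Write records back to the long dialect (inverse of :func:`read_flow_table`)."""
    fmap = dict(DEFAULT_FLAG_MAP if flag_map is None else flag_map)
    reverse = {v: k for k, v in fmap.items()}
    rows = []
    for rec in records:
        for element in FLOW_ELEMENTS:
            if element in rec.flags or rec.get(element) != 0.0:
                flag = rec.flags.get(element, DataFlag.OFFICIAL)
                rows.append(
                    (rec.country, rec.year, rec.commodity, element, rec.get(element), reverse[flag])
                )
    pd.DataFrame(
        rows, columns=["country", "year", "commodity", "element", "value", "flag"]
    ).to_csv(path, index=False)


def flows_to_frame(records: Iterable[CommodityFlowRecord]) -> pd.DataFrame:
    """Wide view of flow records: one row per key, one column per element."""
    rows = [
        {
            "country": r.country,
            "year": r.year,
            "commodity": r.commodity,
            **{e: r.get(e) for e in FLOW_ELEMENTS},
        }
        for r in records
    ]
    cols = ["country", "year", "commodity", *FLOW_ELEMENTS]
    return pd.DataFrame(rows, columns=cols)


SUPPLY_COLUMNS = ("country", "year", "food", "amount_g_day", "basis")


def write_supply_table(records: Iterable[FoodSupply], path: str | Path) -> None:
    """Write per-capita supplies; full float precision (shortest round-trip repr)."""
    rows = [(r.country, r.year, r.food, r.amount, r.basis.value) for r in records]
    pd.DataFrame(rows, columns=list(SUPPLY_COLUMNS)).to_csv(path, index=False)


def read_supply_table(path: str | Path) -> list[FoodSupply]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SUPPLY_COLUMNS, path)
    return [
        FoodSupply(str(r.country), int(r.year), str(r.food), float(r.amount_g_day), Basis(r.basis))
        for r in df.itertuples(index=False)
    ]


def supplies_to_frame(records: Iterable[FoodSupply]) -> pd.DataFrame:
    rows = [(r.country, r.year, r.food, r.amount, r.basis.value) for r in records]
    return pd.DataFrame(rows, columns=list(SUPPLY_COLUMNS))


def read_composition_table(path: str | Path) -> pd.DataFrame:
    """Read a food composition table: ``table_id,food,nutrient,density_per_100g,unit``.

    Densities are per 100 g edible portion, uncooked/least-processed forms.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("table_id", "food", "nutrient", "density_per_100g", "unit"), path)
    bad = df[df["density_per_100g"] < 0]
    if not bad.empty:
        i = bad.index[0]
        raise ParseError(f"{path} row {i}: negative nutrient density")
    return df


def read_table(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    """Generic CSV reader that enforces the presence of named columns."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    _require_columns(df, required, path)
    return df


@dataclasses.dataclass
class PipelineConfig:
    """Everything a full pipeline run needs besides the input tables.

    Parameters
    ----------
    input_dir, out_dir:
        Bundle directory of input CSVs and the directory for stage outputs.
    seed:
        Master seed; every random draw in a run derives from it.
    n_iter:
        Monte Carlo iterations for the nutrient uncertainty intervals.
    exclusion_threshold:
        A country-group reporting this many or fewer non-nes categories is
        dropped from the output.
    reference_diet_kcal:
        Energy level that age-sex normalization adjusts supplies to.
    days_per_year:
        Used when converting tonnes/year to g/person/day.
    target_year:
        Year for the fortification overlay and age-sex stages (most recent
        year of the data when ``None``).
    treat_unofficial_as_redistributable:
        Whether unofficial-flag nes supplies join the redistributable pool
        (default: retained, with a warning).
    nutrients:
        Tracked nutrient names; defaults to the 23-nutrient panel.
    flag_map:
        Raw flag character → internal code.
    """

    input_dir: str = "."
    out_dir: str = "out"
    seed: int = 0
    n_iter: int = 1000
    exclusion_threshold: int = 5
    reference_diet_kcal: float = 2000.0
    days_per_year: float = 365.25
    target_year: int | None = None
    treat_unofficial_as_redistributable: bool = False
    grain_split_basis: str = "edible"  # or "primary"
    apply_voluntary_fortification: bool = True
    nutrients: tuple[str, ...] | None = None
    flag_map: dict[str, str] = dataclasses.field(
        default_factory=lambda: {k: v.value for k, v in DEFAULT_FLAG_MAP.items()}
    )

    def validate(self) -> "PipelineConfig":
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.exclusion_threshold < 0:
            raise ValueError("exclusion_threshold must be >= 0")
        if self.reference_diet_kcal <= 0:
            raise ValueError("reference_diet_kcal must be > 0")
        if self.days_per_year <= 0:
            raise ValueError("days_per_year must be > 0")
        if self.grain_split_basis not in ("edible", "primary"):
            raise ValueError("grain_split_basis must be 'edible' or 'primary'")
        for code in self.flag_map.values():
            DataFlag(code)  # raises on unknown code
        return self

    def resolved_flag_map(self) -> dict[str, DataFlag]:
        return {k: DataFlag(v) for k, v in self.flag_map.items()}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON config file into a validated :class:`PipelineConfig`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    if cfg.nutrients is not None:
        cfg.nutrients = tuple(cfg.nutrients)
    return cfg.validate()


class WarningCollector(logging.Handler):
    """Captures pipeline warnings so the run manifest can list them."""

    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())
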