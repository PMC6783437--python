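"""CSV table contracts and readers/writers.

The pipeline speaks one dialect only: comma-separated, UTF-8, ``.`` decimal,
one header row, element columns named by chemical symbol. Censored cells are
written ``<LOD`` (e.g. ``<0.01``) and substituted at read time under the
configured policy; the pre-substitution censoring mask is kept in
``df.attrs["below_lod"]`` so round-trips preserve the flag.

Missing cells (empty string / NA) mean "not measured" and stay NaN: they are
distinct from below-LOD values and are excluded from medians and
regressions downstream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import ConfigError, ParseError, SchemaError
from .units import (
    MICRONUTRIENTS,
    SOIL_ELEMENTS,
    WATER_MG_PER_L,
    substitute_value,
    water_unit,
)

FOOD_GROUPS = (
    "leafy_veg", "vegetables", "root_tuber", "fruit", "grain",
    "pulses", "maize", "seeds", "nuts",
)
WATER_SOURCES = ("piped", "well", "rainwater", "spring", "borehole", "surface", "undefined")
SEXES = ("F", "M", "both")
SCENARIOS = ("calcareous", "non_calcareous", "published")

#: Water element columns carry their unit in the name; Ca/Mg are mg/L, the
#: trace elements µg/L (the fixed per-element units of the field's tables).
WATER_ELEMENT_COLUMNS = tuple(
    f"{e}_{'mg_L' if e in WATER_MG_PER_L else 'ug_L'}" for e in MICRONUTRIENTS
)


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: tuple[str, ...]
    optional: tuple[str, ...] = ()
    numeric: tuple[str, ...] = ()          # numeric, possibly censored "<lod"
    categorical: dict = field(default_factory=dict)  # column -> allowed values


SCHEMAS: dict[str, TableSchema] = {
    "soil": TableSchema(
        name="soil",
        required=("sample_id", "country", "site_id", "pH", "loi_percent"),
        optional=("lat", "lon", "soil_class") + SOIL_ELEMENTS,
        numeric=("pH", "loi_percent", "lat", "lon") + SOIL_ELEMENTS,
    ),
    "crop": TableSchema(
        name="crop",
        required=("sample_id", "country", "site_id", "food_item", "food_group"),
        optional=MICRONUTRIENTS,
        numeric=MICRONUTRIENTS,
        categorical={"food_group": FOOD_GROUPS},
    ),
    "water": TableSchema(
        name="water",
        required=("sample_id", "country", "source"),
        optional=("pH", "npoc_mg_L", "conductivity_uS_cm", "tds_mg_L") + WATER_ELEMENT_COLUMNS,
        numeric=("pH", "npoc_mg_L", "conductivity_uS_cm", "tds_mg_L") + WATER_ELEMENT_COLUMNS,
        categorical={"source": WATER_SOURCES},
    ),
    "supply": TableSchema(
        name="supply",
        required=("country", "food_item", "fw_supply_g", "moisture_fraction"),
        optional=("dw_supply_g",),
        numeric=("fw_supply_g", "moisture_fraction", "dw_supply_g"),
    ),
    "requirements": TableSchema(
        name="requirements",
        required=("element", "sex"),
        optional=("ear_mg_day", "rni_mg_day", "provenance", "bioavailability_class"),
        numeric=("ear_mg_day", "rni_mg_day"),
        categorical={"sex": SEXES},
    ),
    "composition": TableSchema(
        name="composition",
        required=("scenario", "country", "food_item", "element", "median_mg_kg_dw"),
        optional=("n", "provenance"),
        numeric=("median_mg_kg_dw", "n"),
        categorical={"scenario": SCENARIOS},
    ),
}


def _parse_cell(raw, row: int, col: str):
    """Parse one numeric cell; returns (value, below_lod, lod)."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan, False, math.nan
    s = str(raw).strip()
    if s == "" or s.lower() in {"na", "nan"}:
        return math.nan, False, math.nan
    if s.startswith("<"):
        try:
            lod = float(s[1:])
        except ValueError:
            raise ParseError(f"row {row}, column {col!r}: bad censored value {s!r}") from None
        return math.nan, True, lod
    try:
        return float(s), False, math.nan
    except ValueError:
        raise ParseError(f"row {row}, column {col!r}: non-numeric value {s!r}") from None


def validate_columns(columns: Iterable[str], schema: TableSchema) -> None:
    cols = list(columns)
    missing = [c for c in schema.required if c not in cols]
    if missing:
        raise SchemaError(f"{schema.name} table is missing mandatory column(s): {missing}")
    if schema.name == "water":
        # catch element columns declared under the wrong unit, e.g. Ca_ug_L
        for e in MICRONUTRIENTS:
            good = f"{e}_{'mg_L' if e in WATER_MG_PER_L else 'ug_L'}"
            bad = f"{e}_{'ug_L' if e in WATER_MG_PER_L else 'mg_L'}"
            if bad in cols:
                raise SchemaError(
                    f"water table column {bad!r} uses the wrong unit for {e}; "
                    f"expected {good!r} ({water_unit(e)})"
                )


def read_table(path, schema: str, lod_policy: str = "half_lod") -> pd.DataFrame:
    """Read and validate one pipeline table.

    Returns a DataFrame whose numeric columns are floats with censored cells
    already substituted under ``lod_policy``; ``df.attrs["below_lod"]`` maps
    column -> {row index: detection limit} for the censored cells (plain
    dicts, so the metadata survives pandas merges).
    """
    if schema not in SCHEMAS:
        raise ConfigError(f"unknown table schema {schema!r}; choose from {sorted(SCHEMAS)}")
    sch = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    validate_columns(df.columns, sch)

    out = {}
    censored: dict = {}
    for col in df.columns:
        if col in sch.numeric:
            vals = []
            for i, raw in enumerate(df[col].tolist()):
                v, b, l = _parse_cell(raw, i + 2, col)  # +2: header is line 1
                if b:
                    v = substitute_value(math.nan, True, l, lod_policy)
                    censored.setdefault(col, {})[i] = l
                vals.append(v)
            out[col] = pd.Series(vals, dtype=float)
        else:
            s = df[col].replace({"": pd.NA}).astype("string")
            out[col] = s
    res = pd.DataFrame(out)
    _validate_content(res, sch)
    res.attrs["below_lod"] = censored
    res.attrs["schema"] = schema
    if schema == "supply":
        dw = res["fw_supply_g"] * (1.0 - res["moisture_fraction"])
        if "dw_supply_g" in res.columns and res["dw_supply_g"].notna().any():
            bad = (res["dw_supply_g"] - dw).abs() > 1e-9 * (1 + dw.abs())
            if bad.any():
                raise ParseError(
                    "supply table rows where dw_supply_g != fw_supply_g * (1 - moisture_fraction): "
                    f"rows {sorted((bad[bad].index + 2).tolist())}"
                )
        res["dw_supply_g"] = dw
    return res


def _validate_content(df: pd.DataFrame, sch: TableSchema) -> None:
    for col, allowed in sch.categorical.items():
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = sorted(set(vals) - set(allowed))
        if bad:
            raise ParseError(
                f"{sch.name} table column {col!r} has value(s) outside the closed set "
                f"{allowed}: {bad}"
            )
    if "pH" in df.columns:
        ph = df["pH"].dropna()
        if ((ph <= 0) | (ph >= 14)).any():
            raise ParseError(f"{sch.name} table has pH values outside (0, 14)")
    if "loi_percent" in df.columns:
        loi = df["loi_percent"].dropna()
        if ((loi < 0) | (loi > 100)).any():
            raise ParseError(f"{sch.name} table has loss-on-ignition outside [0, 100]%")
    if "moisture_fraction" in df.columns:
        m = df["moisture_fraction"].dropna()
        if ((m < 0) | (m >= 1)).any():
            raise ParseError(f"{sch.name} table has moisture_fraction outside [0, 1)")
    conc_cols = [c for c in df.columns
                 if c in SOIL_ELEMENTS or c in WATER_ELEMENT_COLUMNS
                 or c in ("median_mg_kg_dw", "fw_supply_g", "ear_mg_day", "rni_mg_day")]
    for col in conc_cols:
        vals = df[col].dropna()
        if (vals < 0).any():
            raise ParseError(f"{sch.name} table column {col!r} has negative values")


def write_table(df: pd.DataFrame, path, schema: Optional[str] = None) -> None:
    """Write a table, re-encoding censored cells as ``<LOD`` strings."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    censored = df.attrs.get("below_lod") or {}
    for col, rows in censored.items():
        if col not in out.columns:
            continue
        col_out = out[col].astype(object)
        for i, lod in rows.items():
            if i in col_out.index:
                col_out.at[i] = f"<{lod:g}"
        out[col] = col_out
    out.to_csv(path, index=False)
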