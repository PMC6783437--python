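"""Shipped default tables: requirements, group map, generator calibration
targets, and a synthetic published-composition source.

Everything here is data, not constants: each loader accepts a path override
so a user can swap in their own table without touching code. Requirement
entries derived from printed values are tagged ``printed`` in the
``source`` column; values back-derived from printed prevalence tables are
tagged ``reconstructed``.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .units import MICRONUTRIENTS


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mnapport").joinpath("data", name)))


def default_requirements(path=None) -> pd.DataFrame:
    """Adult EARs per element x sex, mg/day (µg-scale elements fractional mg).

    Fe and Zn carry the lowest-bioavailability EARs.
    """
    from .io import read_table
    return read_table(path or _data_path("requirements.csv"), "requirements")


def default_group_map(path=None) -> dict:
    """food_item -> food_group mapping."""
    p = Path(path) if path else _data_path("group_map.yaml")
    with open(p, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def default_supply(path=None) -> pd.DataFrame:
    """FBS-style fresh-weight supplies with moisture fractions.

    Maize dry-weight supplies are the study figures (144 g/day Tanzania,
    187 g/day Kenya); other items are standard food-composition defaults
    and are meant to be replaced by user data.
    """
    from .io import read_table
    return read_table(path or _data_path("supply_default.csv"), "supply")


def soil_targets(path=None) -> pd.DataFrame:
    """Generator calibration: per (country, soil class) geometric medians."""
    p = path or _data_path("soil_targets.csv")
    return pd.read_csv(p)


def water_targets(path=None) -> pd.DataFrame:
    """Generator calibration: per (country, source) medians and group sizes."""
    p = path or _data_path("water_targets.csv")
    return pd.read_csv(p)


def crop_targets(path=None) -> pd.DataFrame:
    """Generator calibration: per (country, food item) geometric medians."""
    p = path or _data_path("crop_targets.csv")
    return pd.read_csv(p)


def published_composition(path: Optional[str] = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A synthetic published-composition source and its substitute rows.

    Stands in for external food-composition database inputs: FAO-style
    rows are the crop targets scaled by 0.8 (published values in this
    domain typically undershoot locally measured ones), with maize Se at
    the published figure 0.029 mg/kg; for a few items the trace elements
    (Se, I, Mo) are absent from the FAO-style rows and supplied instead by
    a substitute table, exercising the per-cell provenance mechanics.
    """
    targets = crop_targets(path)
    missing_items = {"pumpkin_leaves", "pigeon_peas", "groundnut"}
    fao_rows, subs = [], []
    for r in targets.itertuples():
        for e in MICRONUTRIENTS:
            val = getattr(r, e)
            if r.food_item == "maize" and e == "Se":
                val = 0.029
            else:
                val = 0.8 * val
            row = {"country": r.country, "food_item": r.food_item,
                   "element": e, "median_mg_kg_dw": val}
            if r.food_item in missing_items and e in ("Se", "I", "Mo"):
                row["median_mg_kg_dw"] = 0.9 * getattr(r, e)
                subs.append(row)
            else:
                fao_rows.append(row)
    return pd.DataFrame(fao_rows), pd.DataFrame(subs)
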