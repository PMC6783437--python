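"""Food composition tables: per-item and per-group median concentrations
(mg kg^-1 dry weight) by country and by the soil class of the source plot.

Three scenarios are first-class: ``calcareous`` and ``non_calcareous``
(measured crops filtered by the linked soil's class) and ``published``
(external food-composition inputs, with gaps filled from a substitute
source and flagged per cell). Group medians pool all underlying samples of
a group rather than taking a median of item medians, which keeps items
measured only once from dominating.
"""
from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .soil import add_soil_class
from .units import MICRONUTRIENTS

logger = logging.getLogger(__name__)

COMPOSITION_COLUMNS = ("scenario", "country", "food_item", "element",
                       "median_mg_kg_dw", "n", "provenance")


def _crops_with_soil_class(crops: pd.DataFrame, soils: pd.DataFrame) -> pd.DataFrame:
    """Attach each crop sample's soil class via site_id; unresolvable sites
    are excluded with a logged count."""
    soils = soils if "soil_class" in soils.columns and not soils["soil_class"].isna().any() \
        else add_soil_class(soils)
    site_class = soils.drop_duplicates("site_id").set_index("site_id")["soil_class"]
    merged = crops.copy()
    merged["soil_class"] = merged["site_id"].map(site_class)
    lost = merged["soil_class"].isna()
    if lost.any():
        logger.warning(
            "%d crop sample(s) excluded: site_id does not resolve to a soil sample (%s)",
            int(lost.sum()), sorted(set(merged.loc[lost, "site_id"].dropna()))[:5],
        )
    return merged[~lost]


def aggregate_by_item(crops: pd.DataFrame, soils: pd.DataFrame, scenario: str,
                      elements=None) -> pd.DataFrame:
    """Median concentration per (country, food_item, element) over crop
    samples whose linked soil matches ``scenario`` (a soil class).

    Returns a long composition table; items with zero samples in the
    scenario are simply absent.
    """
    if scenario not in ("calcareous", "non_calcareous"):
        raise ConfigError(f"measured scenarios are soil classes, got {scenario!r}")
    if elements is None:
        elements = [e for e in MICRONUTRIENTS if e in crops.columns]
    merged = _crops_with_soil_class(crops, soils)
    merged = merged[merged["soil_class"] == scenario]
    rows = []
    for (country, item), g in merged.groupby(["country", "food_item"], sort=True):
        for e in elements:
            vals = g[e].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rows.append({
                "scenario": scenario, "country": country, "food_item": item,
                "element": e, "median_mg_kg_dw": float(np.median(vals)),
                "n": int(vals.size), "provenance": "measured",
            })
    return pd.DataFrame(rows, columns=list(COMPOSITION_COLUMNS))


def aggregate_by_group(crops: pd.DataFrame, soils: pd.DataFrame,
                       group_map: Optional[Mapping[str, str]] = None,
                       scenario: Optional[str] = None,
                       elements=None) -> pd.DataFrame:
    """Food-group medians over the *pooled* crop samples of each group.

    ``group_map`` overrides/supplies the food_item -> food_group mapping;
    otherwise the crop table's own ``food_group`` column is used. With
    ``scenario`` set, samples are first filtered by linked soil class.
    """
    if elements is None:
        elements = [e for e in MICRONUTRIENTS if e in crops.columns]
    merged = crops.copy()
    if scenario is not None:
        merged = _crops_with_soil_class(merged, soils)
        merged = merged[merged["soil_class"] == scenario]
    if group_map is not None:
        unmapped = sorted(set(merged["food_item"].dropna()) - set(group_map))
        if unmapped:
            raise ConfigError(f"food item(s) missing from the group map: {unmapped}")
        merged["food_group"] = merged["food_item"].map(dict(group_map))
    elif merged["food_group"].isna().any():
        raise ConfigError("crop rows without a food_group and no group map supplied")
    rows = []
    for (country, group), g in merged.groupby(["country", "food_group"], sort=True):
        for e in elements:
            vals = g[e].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rows.append({
                "scenario": scenario or "all", "country": country, "food_group": group,
                "element": e, "median_mg_kg_dw": float(np.median(vals)),
                "n": int(vals.size),
            })
    return pd.DataFrame(rows)


def build_published_table(fao_rows: pd.DataFrame,
                          substitutions: Optional[pd.DataFrame] = None,
                          required_items=None) -> pd.DataFrame:
    """Assemble the published-composition scenario.

    ``fao_rows`` and ``substitutions`` are long tables with columns
    (country, food_item, element, median_mg_kg_dw). Cells present in
    ``fao_rows`` are flagged ``measured``; gaps filled from
    ``substitutions`` are flagged ``substituted``. An item in
    ``required_items`` absent from both sources is a hard error.
    """
    key = ["country", "food_item", "element"]
    fao = fao_rows.copy()
    fao["provenance"] = "measured"
    parts = [fao]
    if substitutions is not None and not substitutions.empty:
        sub = substitutions.copy()
        sub["provenance"] = "substituted"
        have = set(map(tuple, fao[key].itertuples(index=False)))
        sub = sub[[tuple(r) not in have for r in sub[key].itertuples(index=False)]]
        parts.append(sub)
    out = pd.concat(parts, ignore_index=True)
    out["scenario"] = "published"
    if "n" not in out.columns:
        out["n"] = np.nan
    if required_items is not None:
        missing = sorted(set(required_items) - set(out["food_item"]))
        if missing:
            raise DataError(
                f"food item(s) absent from both published and substitute sources: {missing}"
            )
    return out[list(COMPOSITION_COLUMNS)]
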