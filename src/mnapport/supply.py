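"""Dietary supply model: composition x food-balance-sheet supply.

Supplies are computed in dry-weight space: fresh-weight supply
(g capita^-1 day^-1) is moisture-corrected to dry weight, multiplied by the
item's dry-weight concentration (mg kg^-1) and summed over items to give
the per-element total supply in mg capita^-1 day^-1. Items without
composition data in a scenario are dropped from that scenario (never
imputed) and a fresh-weight mass completeness ratio records the coverage.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError
from .units import MICRONUTRIENTS

logger = logging.getLogger(__name__)


def item_supply(dw_supply_g: float, conc_mg_kg_dw: float) -> float:
    """Daily element mass from one food item, mg day^-1.

    ``dw_supply_g`` g/day of dry matter at ``conc_mg_kg_dw`` mg/kg:
    g x mg/kg = µg... careful with the factor: mg/kg == mg per 1000 g, so
    the daily mass is dw_supply_g * conc / 1000 mg.
    """
    if dw_supply_g < 0 or conc_mg_kg_dw < 0:
        raise DataError("supply and concentration must be non-negative")
    return dw_supply_g * conc_mg_kg_dw / 1000.0


@dataclass
class SupplyScenario:
    """Per-element dietary supply for one country x composition scenario."""

    country: str
    scenario: str
    per_item: pd.DataFrame                 # food_item, element, supply_mg_day
    total: dict = field(default_factory=dict)   # element -> mg/day
    completeness: float = 0.0              # fraction of FW supply mass covered
    dropped_items: tuple = ()


def total_supply(composition: pd.DataFrame, supply: pd.DataFrame,
                 country: str, scenario: str,
                 elements=MICRONUTRIENTS) -> SupplyScenario:
    """Sum per-item supplies for one country under one composition scenario.

    ``composition`` is a long table (scenario, country, food_item, element,
    median_mg_kg_dw); ``supply`` carries fw_supply_g, moisture_fraction and
    the derived dw_supply_g per item.
    """
    comp = composition[(composition["scenario"] == scenario)
                       & (composition["country"] == country)]
    sup = supply[supply["country"] == country].copy()
    if "dw_supply_g" not in sup.columns:
        sup["dw_supply_g"] = sup["fw_supply_g"] * (1.0 - sup["moisture_fraction"])

    conc = {(r.food_item, r.element): r.median_mg_kg_dw for r in comp.itertuples()}
    covered_items = {item for item, _ in conc}
    dropped = tuple(sorted(set(sup["food_item"]) - covered_items))
    if dropped:
        logger.warning(
            "%s/%s: %d supply item(s) lack composition data and are dropped: %s",
            country, scenario, len(dropped), dropped,
        )
    fw_total = float(sup["fw_supply_g"].sum())
    fw_covered = float(sup.loc[sup["food_item"].isin(covered_items), "fw_supply_g"].sum())
    completeness = fw_covered / fw_total if fw_total > 0 else 0.0

    rows = []
    totals = {e: 0.0 for e in elements}
    for r in sup.itertuples():
        if r.food_item not in covered_items:
            continue
        for e in elements:
            c = conc.get((r.food_item, e))
            if c is None:
                continue
            s = item_supply(r.dw_supply_g, c)
            totals[e] += s
            rows.append({"food_item": r.food_item, "element": e,
                         "supply_mg_day": s})
    per_item = pd.DataFrame(rows, columns=["food_item", "element", "supply_mg_day"])
    return SupplyScenario(country=country, scenario=scenario, per_item=per_item,
                          total=totals, completeness=completeness,
                          dropped_items=dropped)


def supply_table(scenarios) -> pd.DataFrame:
    """Flatten SupplyScenario objects into the supply_scenario.csv layout."""
    rows = []
    for sc in scenarios:
        for e, v in sc.total.items():
            rows.append({"country": sc.country, "scenario": sc.scenario,
                         "element": e, "total_mg_capita_day": v,
                         "completeness": sc.completeness})
    return pd.DataFrame(rows)
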