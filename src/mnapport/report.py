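"""Pipeline driver: run every stage on a directory of input tables and
write the report CSVs plus a run manifest.

All rounding happens here and in the ``*_rounded`` columns; machine
outputs keep full precision.
"""
from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, defaults
from .composition import aggregate_by_group, aggregate_by_item, build_published_table
from .errors import ConfigError
from .io import read_table
from .lmg import build_design, decompose_design, decomposition_report
from .risk import RequirementPolicy, build_risk_table, risk_report
from .soil import add_soil_class, soil_summary_table, summarise_soils
from .supply import supply_table, total_supply
from .units import MICRONUTRIENTS
from .water import DEFAULT_VOLUME_L_DAY, contribution_table, summarise_water

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run."""

    in_dir: Optional[str] = None
    out_dir: str = "outputs"
    scenarios: tuple = ("calcareous", "non_calcareous", "published")
    cv_intake: float = 0.25
    distribution: str = "normal"
    rni_divisor: float = 1.2
    water_volume_L: float = DEFAULT_VOLUME_L_DAY
    lod_policy: str = "half_lod"
    seed: int = 0
    min_regression_n: int = 13    # predictors + 2 for the full 11-slot panel
    extra: dict = field(default_factory=dict)

    def policy(self) -> RequirementPolicy:
        return RequirementPolicy(rni_to_ear_divisor=self.rni_divisor,
                                 cv_intake=self.cv_intake,
                                 distribution=self.distribution)


def _load_inputs(config: PipelineConfig) -> dict:
    if config.in_dir is None:
        raise ConfigError("pipeline requires an input directory")
    d = Path(config.in_dir)
    tables = {}
    for name, schema in (("soil", "soil"), ("crop", "crop"), ("water", "water"),
                         ("supply", "supply"), ("requirements", "requirements")):
        p = d / f"{name}.csv"
        if not p.exists():
            if name == "requirements":
                tables[name] = defaults.default_requirements()
                continue
            raise ConfigError(f"missing input table: {p}")
        tables[name] = read_table(p, schema, lod_policy=config.lod_policy)
    for name in ("published_fao", "published_substitutions"):
        p = d / f"{name}.csv"
        tables[name] = pd.read_csv(p) if p.exists() else None
    return tables


def run_pipeline(config: PipelineConfig) -> dict:
    """Run classify -> aggregate -> supply -> risk -> water -> regress and
    write every report table under ``config.out_dir``. Returns the tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = _load_inputs(config)
    soils = add_soil_class(tables["soil"])
    crops, water, supply, requirements = (tables["crop"], tables["water"],
                                          tables["supply"], tables["requirements"])
    results: dict = {}

    results["soil_summary"] = soil_summary_table(soils)
    results["soil_summary_full"] = summarise_soils(soils)

    comp_parts = []
    for scenario in config.scenarios:
        if scenario == "published":
            if tables["published_fao"] is None:
                logger.warning("no published composition inputs; scenario skipped")
                continue
            comp_parts.append(build_published_table(
                tables["published_fao"], tables["published_substitutions"]))
        else:
            comp_parts.append(aggregate_by_item(crops, soils, scenario))
    composition = pd.concat(comp_parts, ignore_index=True)
    results["composition"] = composition
    results["group_composition"] = pd.concat(
        [aggregate_by_group(crops, soils, scenario=s)
         for s in ("calcareous", "non_calcareous")], ignore_index=True)

    scenarios = []
    for country in sorted(supply["country"].dropna().unique()):
        for scenario in sorted(composition["scenario"].dropna().unique()):
            if ((composition["scenario"] == scenario)
                    & (composition["country"] == country)).any():
                scenarios.append(total_supply(composition, supply, country, scenario))
    results["supply_scenario"] = supply_table(scenarios)

    risk = build_risk_table(scenarios, requirements, config.policy())
    results["risk_table"] = risk
    results["risk_table_wide"] = risk_report(risk)

    wsum = summarise_water(water)
    results["water_summary"] = wsum
    results["water_contribution"] = contribution_table(
        wsum, requirements, volume_L=config.water_volume_L, policy=config.policy())

    decomp = []
    for group in sorted(crops["food_group"].dropna().unique()):
        for element in MICRONUTRIENTS:
            if element not in crops.columns:
                continue
            design = build_design(crops, soils, group, element)
            if len(design.y) < config.min_regression_n:
                continue
            decomp.append(decompose_design(design))
    if decomp:
        results["variance_table"] = decomposition_report(decomp)

    for name, df in results.items():
        df.to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "package": "mnapport",
        "version": __version__,
        "python": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": {k: v for k, v in vars(config).items() if k != "extra"},
        "row_counts": {k: int(len(v)) for k, v in results.items()},
        "input_rows": {k: int(len(v)) for k, v in tables.items() if v is not None},
    }
    manifest["config"]["scenarios"] = list(config.scenarios)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
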