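"""Soil classification and median summaries.

Soils are classified operationally by pH: calcareous where pH > 6.5
(strictly), non-calcareous otherwise, including at the boundary. The
summary reproduces the survey-style table of per-group medians with
quartiles computed by linear interpolation between order statistics
(numpy's default, the "type 7" convention).
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import DataError
from .units import MICRONUTRIENTS, SOIL_ELEMENTS

CALCAREOUS_PH_THRESHOLD = 6.5


def classify_soil(pH: float) -> str:
    """Classify one soil by pH: ``calcareous`` iff pH > 6.5 (strict)."""
    if not math.isfinite(pH):
        raise DataError(f"pH must be finite, got {pH!r}")
    if not (0 < pH < 14):
        raise DataError(f"pH must lie in (0, 14), got {pH}")
    return "calcareous" if pH > CALCAREOUS_PH_THRESHOLD else "non_calcareous"


def add_soil_class(soils: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``soil_class`` column derived from pH."""
    out = soils.copy()
    out["soil_class"] = [classify_soil(p) for p in out["pH"]]
    return out


def summarise_soils(soils: pd.DataFrame, elements=None,
                    quartiles: bool = True) -> pd.DataFrame:
    """Per (country, soil_class) group medians of pH, LOI and elements.

    Missing concentrations (not-measured cells) are excluded per element;
    group counts report the number of contributing soil samples. Output is
    one row per group with ``median_<el>`` and optionally ``q1_<el>`` /
    ``q3_<el>`` columns.
    """
    if elements is None:
        elements = [e for e in SOIL_ELEMENTS if e in soils.columns]
    if soils.empty:
        return pd.DataFrame(columns=["country", "soil_class", "n"])
    if "soil_class" not in soils.columns or soils["soil_class"].isna().any():
        soils = add_soil_class(soils)
    rows = []
    for (country, soil_class), g in soils.groupby(["country", "soil_class"], sort=True):
        row: dict = {"country": country, "soil_class": soil_class, "n": len(g)}
        row["median_pH"] = float(np.nanmedian(g["pH"]))
        row["median_loi_percent"] = float(np.nanmedian(g["loi_percent"]))
        for e in elements:
            vals = g[e].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                row[f"median_{e}"] = np.nan
                if quartiles:
                    row[f"q1_{e}"] = np.nan
                    row[f"q3_{e}"] = np.nan
                continue
            row[f"median_{e}"] = float(np.median(vals))
            if quartiles:
                q1, q3 = np.quantile(vals, [0.25, 0.75])  # type-7 interpolation
                row[f"q1_{e}"] = float(q1)
                row[f"q3_{e}"] = float(q3)
        rows.append(row)
    return pd.DataFrame(rows)


def soil_summary_table(soils: pd.DataFrame) -> pd.DataFrame:
    """Publication-layout summary: country x class rows, micronutrient
    median columns only (no quartiles)."""
    summary = summarise_soils(soils, elements=list(MICRONUTRIENTS), quartiles=False)
    cols = ["country", "soil_class", "n", "median_pH", "median_loi_percent"] + [
        f"median_{e}" for e in MICRONUTRIENTS if f"median_{e}" in summary.columns
    ]
    return summary[cols]
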