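"""Drinking-water chemistry summaries and contribution to the EAR.

Water is summarised per (country, source) as element medians in the fixed
per-element units (mg/L for Ca and Mg, µg/L for the traces). The potential
contribution of a source to the requirement assumes a fixed daily
consumption volume (default 1.7 L, a deliberately conservative figure for
hot climates):

    %EAR = 100 * (median_conc as mg/L) * volume_L / EAR_mg_day

Maximum-concentration ("up to") contributions are computed alongside the
medians because headline figures for sporadically contaminated sources
(e.g. roof-collected rainwater Zn) rest on maxima, not medians.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError
from .risk import RequirementPolicy, expand_requirements
from .units import (
    MICRONUTRIENTS,
    Concentration,
    round_half_up,
    to_canonical_mg_day,
    water_unit,
)

DEFAULT_VOLUME_L_DAY = 1.7


def _element_column(element: str) -> str:
    return f"{element}_{'mg_L' if water_unit(element) == 'mg_per_L' else 'ug_L'}"


def summarise_water(samples: pd.DataFrame, elements=MICRONUTRIENTS) -> pd.DataFrame:
    """Median (and max) concentration per (country, source, element) with n.

    Medians are over non-missing values; units follow the fixed per-element
    convention and are recorded in the ``unit`` column.
    """
    rows = []
    if samples.empty:
        return pd.DataFrame(columns=["country", "source", "element", "unit",
                                     "n", "median_conc", "max_conc"])
    for (country, source), g in samples.groupby(["country", "source"], sort=True):
        for e in elements:
            col = _element_column(e)
            if col not in g.columns:
                continue
            vals = g[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rows.append({
                "country": country, "source": source, "element": e,
                "unit": water_unit(e), "n": int(vals.size),
                "median_conc": float(np.median(vals)),
                "max_conc": float(np.max(vals)),
            })
    return pd.DataFrame(rows)


def percent_of_ear(median_conc: Concentration, volume_L: float,
                   ear_mg_day: float) -> float:
    """Percentage of the EAR supplied by drinking ``volume_L`` per day."""
    if ear_mg_day <= 0:
        raise ConfigError(f"EAR must be positive, got {ear_mg_day}")
    return 100.0 * to_canonical_mg_day(median_conc, volume_L) / ear_mg_day


def contribution_table(water_summary: pd.DataFrame, requirements: pd.DataFrame,
                       volume_L: float = DEFAULT_VOLUME_L_DAY,
                       policy: RequirementPolicy = RequirementPolicy(),
                       stat: str = "median_conc") -> pd.DataFrame:
    """Per (country, source, element, sex) contribution to the EAR.

    ``stat`` selects the summarised concentration column (``median_conc``
    or ``max_conc``). ``percent_rounded`` mirrors the one-decimal half-up
    presentation of the printed tables.
    """
    if stat not in water_summary.columns:
        raise ConfigError(f"water summary has no column {stat!r}")
    ears = expand_requirements(requirements, policy)
    ear_map = {(r.element, r.sex): r.ear_mg_day for r in ears.itertuples()}
    rows = []
    for r in water_summary.itertuples():
        conc = Concentration(getattr(r, stat), r.unit)
        intake = to_canonical_mg_day(conc, volume_L)
        for sex in ("F", "M"):
            if (r.element, sex) not in ear_map:
                raise ConfigError(f"no requirement for ({r.element}, {sex})")
            ear = ear_map[(r.element, sex)]
            pct = percent_of_ear(conc, volume_L, ear)
            rows.append({
                "country": r.country, "source": r.source, "element": r.element,
                "sex": sex, "median_conc": getattr(r, stat), "unit": r.unit,
                "volume_L_day": volume_L, "intake_mg_day": intake,
                "ear_mg_day": ear, "percent_of_ear": pct,
                "percent_rounded": round_half_up(pct, 1),
            })
    return pd.DataFrame(rows)


def volume_sensitivity(water_summary: pd.DataFrame, requirements: pd.DataFrame,
                       volumes_L=(1.0, 1.7, 2.5, 3.5),
                       policy: RequirementPolicy = RequirementPolicy()) -> pd.DataFrame:
    """Contribution table recomputed over a grid of daily volumes."""
    parts = []
    for v in volumes_L:
        t = contribution_table(water_summary, requirements, volume_L=v, policy=policy)
        parts.append(t)
    return pd.concat(parts, ignore_index=True)
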