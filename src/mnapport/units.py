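"""Element identifiers, concentration values, unit conversion and the
below-detection-limit substitution policy.

All dietary intakes and requirements are carried internally in
mg day^-1; µg-scale elements (Se, I, Mo) are stored as fractional mg.
Report layers rescale for display.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .errors import ConfigError, DataError

#: The micronutrients this pipeline tracks through diet and water.
MICRONUTRIENTS: tuple[str, ...] = ("Ca", "Cu", "Fe", "Mg", "Zn", "Se", "I", "Mo")

#: Additional soil elements used only as regression predictors.
SOIL_PREDICTOR_ELEMENTS: tuple[str, ...] = ("Mn", "Al", "K", "P", "S")

#: Every element symbol a soil table may carry.
SOIL_ELEMENTS: tuple[str, ...] = MICRONUTRIENTS + SOIL_PREDICTOR_ELEMENTS

#: Elements reported in mg L^-1 in water tables; the rest are µg L^-1.
WATER_MG_PER_L: tuple[str, ...] = ("Ca", "Mg")

#: Concentration units understood by the pipeline.
UNITS = ("mg_per_kg_dw", "mg_per_L", "ug_per_L")

#: Below-LOD substitution policies.
LOD_POLICIES = ("half_lod", "zero", "lod")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention of the printed tables.

    Python's built-in ``round`` is banker's rounding; report tables here
    use half-up (89.5 -> 90, 74.45 -> 74.5 at one decimal).
    """
    x = float(x)
    if not math.isfinite(x):
        raise DataError(f"cannot round non-finite value {x!r}")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Concentration:
    """One measured concentration with its unit and censoring state.

    If ``below_lod`` is set, ``lod`` must be present and ``value`` holds the
    output of the substitution policy applied at parse time.
    """

    value: float
    unit: str
    below_lod: bool = False
    lod: Optional[float] = None

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise DataError(f"unknown concentration unit {self.unit!r}")
        if not math.isfinite(self.value) or self.value < 0:
            raise DataError(f"concentration must be finite and >= 0, got {self.value!r}")
        if self.below_lod and self.lod is None:
            raise DataError("below-LOD concentration without a detection limit")


def substitute_below_lod(c: Concentration, policy: str = "half_lod") -> Concentration:
    """Apply a censored-value substitution policy.

    Non-censored values pass through unchanged. ``half_lod`` stores lod/2,
    ``zero`` stores 0, ``lod`` stores the detection limit itself.
    """
    if policy not in LOD_POLICIES:
        raise ConfigError(f"unknown below-LOD policy {policy!r}; choose from {LOD_POLICIES}")
    if not c.below_lod:
        return c
    if c.lod is None:
        raise DataError("below-LOD concentration without a detection limit")
    value = {"half_lod": c.lod / 2.0, "zero": 0.0, "lod": c.lod}[policy]
    return replace(c, value=value)


def substitute_value(raw: float, below_lod: bool, lod: Optional[float],
                     policy: str = "half_lod") -> float:
    """Scalar form of :func:`substitute_below_lod` for table parsing."""
    if policy not in LOD_POLICIES:
        raise ConfigError(f"unknown below-LOD policy {policy!r}; choose from {LOD_POLICIES}")
    if not below_lod:
        return raw
    if lod is None:
        raise DataError("below-LOD value without a detection limit")
    return {"half_lod": lod / 2.0, "zero": 0.0, "lod": lod}[policy]


def to_canonical_mg_day(amount: Concentration, volume_L: float) -> float:
    """Convert a water concentration drunk at ``volume_L`` L/day to mg/day."""
    if volume_L < 0:
        raise DataError(f"consumption volume must be >= 0, got {volume_L}")
    if amount.unit == "mg_per_L":
        return amount.value * volume_L
    if amount.unit == "ug_per_L":
        return amount.value * volume_L / 1000.0
    raise DataError(
        f"cannot convert a {amount.unit} concentration to a daily mass; "
        "expected mg_per_L or ug_per_L"
    )


def water_unit(element: str) -> str:
    """The fixed reporting unit for an element in water tables."""
    return "mg_per_L" if element in WATER_MG_PER_L else "ug_per_L"
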