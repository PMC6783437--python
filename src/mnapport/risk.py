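"""EAR cut-point model: % of the population at risk of deficiency.

The population intake of an element is modelled as a distribution centred
on the per-capita supply S with a fixed coefficient of variation (default
25%); the prevalence of inadequate intake is the mass of that distribution
below the Estimated Average Requirement:

    risk% = 100 * Phi((EAR - S) / (cv * S))        (normal intakes)

A log-normal alternative (same mean and CV) is available behind the
``distribution`` switch. Requirements available only as Recommended
Nutrient Intakes are converted with EAR = RNI / divisor, divisor
1.2 = 1 + 2 x 0.10 by the usual FAO/WHO convention. For Fe and Zn the EAR
for the lowest dietary bioavailability is assumed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, DataError
from .units import round_half_up

logger = logging.getLogger(__name__)


def convert_rni_to_ear(rni_mg_day: float, divisor: float = 1.2) -> float:
    """EAR from an RNI: ``rni / divisor``; divisor must exceed 1."""
    if rni_mg_day <= 0:
        raise DataError(f"RNI must be positive, got {rni_mg_day}")
    if divisor <= 1:
        raise ConfigError(f"RNI->EAR divisor must exceed 1, got {divisor}")
    return rni_mg_day / divisor


def risk_percent(S, EAR, cv: float = 0.25, distribution: str = "normal"):
    """Percentage of the population with intake below the EAR.

    ``S`` and ``EAR`` are in the same units (canonically mg day^-1) and may
    be scalars or arrays. ``S = 0`` returns 100 by convention (logged).
    """
    if not (0 < cv < 1):
        raise ConfigError(f"intake CV must lie in (0, 1), got {cv}")
    S = np.asarray(S, dtype=float)
    EAR = np.asarray(EAR, dtype=float)
    if (S < 0).any() or (EAR <= 0).any():
        raise DataError("supply must be >= 0 and EAR > 0")
    zero = S == 0
    if zero.any():
        logger.warning("zero supply: risk set to 100%% for %d case(s)", int(zero.sum()))
    Ssafe = np.where(zero, 1.0, S)
    if distribution == "normal":
        z = (EAR - Ssafe) / (cv * Ssafe)
        out = 100.0 * norm.cdf(z)
    elif distribution == "lognormal":
        sigma2 = math.log1p(cv * cv)
        sigma = math.sqrt(sigma2)
        mu = np.log(Ssafe) - sigma2 / 2.0
        out = 100.0 * norm.cdf((np.log(EAR) - mu) / sigma)
    else:
        raise ConfigError(f"unknown intake distribution {distribution!r}")
    out = np.where(zero, 100.0, out)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RequirementPolicy:
    """How requirement inputs become per-sex EARs."""

    rni_to_ear_divisor: float = 1.2
    cv_intake: float = 0.25
    distribution: str = "normal"

    def __post_init__(self):
        if self.rni_to_ear_divisor <= 1:
            raise ConfigError("rni_to_ear_divisor must exceed 1")


def expand_requirements(requirements: pd.DataFrame,
                        policy: RequirementPolicy = RequirementPolicy()) -> pd.DataFrame:
    """Resolve the requirements table to one EAR per (element, sex in {F, M}).

    Rows with ``sex = both`` are duplicated to F and M. Rows lacking
    ``ear_mg_day`` but carrying ``rni_mg_day`` are converted.
    """
    rows = []
    for r in requirements.itertuples():
        ear = getattr(r, "ear_mg_day", math.nan)
        rni = getattr(r, "rni_mg_day", math.nan)
        if ear is None or (isinstance(ear, float) and math.isnan(ear)):
            if rni is None or (isinstance(rni, float) and math.isnan(rni)):
                raise ConfigError(
                    f"requirement for ({r.element}, {r.sex}) has neither EAR nor RNI")
            ear = convert_rni_to_ear(float(rni), policy.rni_to_ear_divisor)
            provenance = "converted_from_rni"
        else:
            ear = float(ear)
            provenance = getattr(r, "provenance", None) or "direct_ear"
        sexes = ("F", "M") if r.sex == "both" else (r.sex,)
        for sex in sexes:
            rows.append({"element": r.element, "sex": sex, "ear_mg_day": ear,
                         "provenance": provenance})
    out = pd.DataFrame(rows)
    dup = out.duplicated(["element", "sex"])
    if dup.any():
        raise ConfigError(
            f"duplicate requirement rows after sex expansion: "
            f"{out.loc[dup, ['element', 'sex']].to_records(index=False).tolist()}")
    return out


def build_risk_table(scenarios, requirements: pd.DataFrame,
                     policy: RequirementPolicy = RequirementPolicy()) -> pd.DataFrame:
    """One risk estimate per country x scenario x sex x element.

    ``scenarios`` is an iterable of :class:`~mnapport.supply.SupplyScenario`.
    ``risk_percent`` carries full precision; ``risk_rounded`` is the
    half-up integer used in report tables.
    """
    ears = expand_requirements(requirements, policy)
    ear_map = {(r.element, r.sex): r.ear_mg_day for r in ears.itertuples()}
    rows = []
    for sc in scenarios:
        for element, S in sc.total.items():
            for sex in ("F", "M"):
                if (element, sex) not in ear_map:
                    raise ConfigError(
                        f"no requirement for ({element}, {sex}) after sex expansion")
                ear = ear_map[(element, sex)]
                r = risk_percent(S, ear, cv=policy.cv_intake,
                                 distribution=policy.distribution)
                rows.append({
                    "country": sc.country, "scenario": sc.scenario, "sex": sex,
                    "element": element, "supply_mg_day": S, "ear_mg_day": ear,
                    "cv_intake": policy.cv_intake, "risk_percent": r,
                    "risk_rounded": int(round_half_up(r)),
                })
    return pd.DataFrame(rows)


def risk_report(risk_table: pd.DataFrame) -> pd.DataFrame:
    """Publication-layout risk table: scenario x sex rows, element columns,
    integer percentages."""
    wide = risk_table.pivot_table(index=["country", "scenario", "sex"],
                                  columns="element", values="risk_rounded",
                                  aggfunc="first")
    return wide.reset_index()
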