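"""Relative importance of soil predictors for crop chemistry.

Per food group x element, the log crop concentration is regressed on a
fixed panel of 11 soil predictors (the same element's soil concentration,
pH, organic matter, and soil Fe, Mn, Al, Ca, Mg, K, P, S; element
concentrations natural-log transformed, pH and OM raw). The model R^2 is
then attributed to individual predictors by the LMG method: the average,
over all orderings of the predictors, of the sequential increase in R^2
when the predictor enters. Averaging over orderings collapses to a sum
over subsets,

    share(k) = (1/p) * sum over S subset of others
               [ C(p-1, |S|)^-1 * (R^2(S u {k}) - R^2(S)) ],

so one pass over the 2^p subset R^2 values replaces the p! enumeration.
Shares are reported in percentage points of variance and sum exactly to
100 * R^2 of the full model. Significance and direction come from the
full-model coefficient t-tests; the "dominant" predictor is the largest
share among those significant at 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, DataError
from .soil import add_soil_class

#: The 11 predictor slots, in report order. ``soil_element`` is the soil
#: concentration of the response element itself.
PREDICTOR_SLOTS = ("soil_element", "pH", "OM",
                   "Fe", "Mn", "Al", "Ca", "Mg", "K", "P", "S")
_NAMED_ELEMENT_SLOTS = ("Fe", "Mn", "Al", "Ca", "Mg", "K", "P", "S")


def _safe_log(a: np.ndarray) -> np.ndarray:
    """ln(a) with zero/negative values mapped to NaN (row is dropped later)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log(a)
    out[~np.isfinite(out)] = np.nan
    return out


@dataclass
class DesignMatrix:
    """Paired design for one (food_group, element) regression."""

    food_group: str
    element: str
    X: pd.DataFrame           # columns = predictor slots after dedup
    y: pd.Series              # ln crop concentration
    n_dropped: int
    degenerate: bool = False
    dropped_slot: Optional[str] = None


@dataclass
class DecompositionResult:
    """LMG shares with inference flags for one fitted model."""

    food_group: str
    element: str
    table: pd.DataFrame       # index predictor; share_percent, p_value,
                              # direction, significant, dominant
    total_variance_percent: float
    n: int
    degenerate: bool = False


def build_design(crops: pd.DataFrame, soils: pd.DataFrame, food_group: str,
                 element: str,
                 predictors: Sequence[str] = PREDICTOR_SLOTS) -> DesignMatrix:
    """Pair crop samples of one food group with their site's soil chemistry.

    Response: ln(crop concentration of ``element``). Element predictors are
    ln(soil concentration); pH and OM (loss-on-ignition) enter raw. When the
    same-element slot duplicates a named slot (response element in the soil
    panel) the named slot is dropped. Rows with any missing or non-positive
    value in a used column are dropped and counted.
    """
    if element not in crops.columns:
        raise ConfigError(f"crop table has no {element!r} column")
    soils = soils if "soil_class" in soils.columns else add_soil_class(soils)
    sub = crops[crops["food_group"] == food_group]
    soil_cols = ["site_id", "pH", "loi_percent"] + [
        e for e in set(_NAMED_ELEMENT_SLOTS) | {element} if e in soils.columns
    ]
    merged = sub.merge(soils[soil_cols].drop_duplicates("site_id"),
                       on="site_id", how="inner", suffixes=("", "_soil"))

    slots = list(predictors)
    dropped_slot = None
    if element in slots and "soil_element" in slots:
        slots.remove(element)            # dedup: same-element slot wins
        dropped_slot = element

    cols = {}
    # crop pH column would collide with soil pH after the merge; soil pH
    # keeps the bare name because crops carry no pH column.
    soil_elem_col = element if element not in sub.columns else f"{element}_soil"
    for s in slots:
        if s == "soil_element":
            cols[s] = _safe_log(merged[soil_elem_col].to_numpy(dtype=float))
        elif s == "pH":
            cols[s] = merged["pH"].to_numpy(dtype=float)
        elif s == "OM":
            cols[s] = merged["loi_percent"].to_numpy(dtype=float)
        else:
            # crop and soil tables share element names; after the merge the
            # soil copy carries the _soil suffix wherever they collide
            col = f"{s}_soil" if s in sub.columns else s
            if col not in merged.columns:
                raise ConfigError(f"soil table has no {s!r} column for predictor slot")
            cols[s] = _safe_log(merged[col].to_numpy(dtype=float))

    y = _safe_log(merged[element].to_numpy(dtype=float))
    X = pd.DataFrame(cols)
    ok = np.isfinite(y)
    for s in X.columns:
        ok &= np.isfinite(X[s].to_numpy())
    n_dropped = int((~ok).sum())
    X = X.loc[ok].reset_index(drop=True)
    yv = pd.Series(y[ok], name=f"ln_{element}")
    degenerate = len(yv) < len(slots) + 2
    return DesignMatrix(food_group=food_group, element=element, X=X, y=yv,
                        n_dropped=n_dropped, degenerate=degenerate,
                        dropped_slot=dropped_slot)


def _all_subset_r2(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """R^2 of every predictor subset, indexed by bitmask (length 2^p).

    Works on centred cross-products: R^2(S) = c_S' G_S^{-1} c_S / var(y).
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    syy = float(yc @ yc)
    if syy <= 0:
        raise DataError("response has zero variance")
    G = Xc.T @ Xc
    c = Xc.T @ yc
    r2 = np.empty(1 << p)
    r2[0] = 0.0
    for mask in range(1, 1 << p):
        idx = [j for j in range(p) if mask >> j & 1]
        Gs = G[np.ix_(idx, idx)]
        cs = c[idx]
        try:
            beta = np.linalg.solve(Gs, cs)
        except np.linalg.LinAlgError:
            raise DataError("rank-deficient design: collinear predictor subset") from None
        r2[mask] = float(cs @ beta) / syy
    return r2


def lmg_shares(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """LMG shares (fractions of variance) and the full-model R^2."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 1:
        raise ConfigError("need at least one predictor")
    if n < p + 2:
        raise DataError(f"need n >= p + 2 observations, got n={n}, p={p}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        raise DataError("design matrix is rank deficient")
    r2 = _all_subset_r2(X, y)
    # weight of a subset of given size among the other p-1 predictors
    w = np.array([1.0 / (p * comb(p - 1, s)) for s in range(p)])
    masks = np.arange(1 << p)
    popcount = np.zeros(1 << p, dtype=np.int64)
    for j in range(p):
        popcount += (masks >> j) & 1
    shares = np.empty(p)
    for k in range(p):
        kbit = 1 << k
        without = masks[(masks & kbit) == 0]
        inc = r2[without | kbit] - r2[without]
        shares[k] = float(inc @ w[popcount[without]])
    return shares, float(r2[(1 << p) - 1])


def lmg_decompose(X, y, names: Optional[Sequence[str]] = None,
                  alpha: float = 0.05, food_group: str = "",
                  element: str = "") -> DecompositionResult:
    """Full decomposition with inference for one design.

    ``X`` may be a DataFrame (column names used) or array with ``names``.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if names is None:
            names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float)
    shares, r2_full = lmg_shares(Xa, ya)

    fit = sm.OLS(ya, sm.add_constant(Xa)).fit()
    pvals = fit.pvalues[1:]
    coefs = fit.params[1:]

    significant = pvals < alpha
    dominant = np.zeros(len(names), dtype=bool)
    if significant.any():
        sig_idx = np.flatnonzero(significant)
        dominant[sig_idx[np.argmax(shares[sig_idx])]] = True

    table = pd.DataFrame({
        "share_percent": shares * 100.0,
        "p_value": pvals,
        "direction": np.where(coefs >= 0, "+", "-"),
        "significant": significant,
        "dominant": dominant,
    }, index=pd.Index(names, name="predictor"))
    return DecompositionResult(food_group=food_group, element=element,
                               table=table,
                               total_variance_percent=r2_full * 100.0,
                               n=len(ya))


def decompose_design(design: DesignMatrix, alpha: float = 0.05) -> DecompositionResult:
    """Decompose a built design; degenerate designs yield an empty result."""
    if design.degenerate:
        return DecompositionResult(
            food_group=design.food_group, element=design.element,
            table=pd.DataFrame(columns=["share_percent", "p_value", "direction",
                                        "significant", "dominant"]),
            total_variance_percent=float("nan"), n=len(design.y), degenerate=True)
    return lmg_decompose(design.X, design.y, alpha=alpha,
                         food_group=design.food_group, element=design.element)


def _format_cell(share: float, p_sig: bool, dominant: bool, direction: str) -> str:
    star = "**" if dominant else ("*" if p_sig else "")
    sign = " (-)" if direction == "-" else ""
    return f"{share:.2f}{star}{sign}"


def decomposition_report(results: Sequence[DecompositionResult]) -> pd.DataFrame:
    """Publication-layout matrix per food group: predictor rows (plus a
    total row), element columns, cells ``share[*|**][ (-)]``.

    Degenerate models render as blank columns flagged in the total row.
    """
    frames = []
    for group in sorted({r.food_group for r in results}):
        group_res = [r for r in results if r.food_group == group]
        data: dict = {}
        for r in sorted(group_res, key=lambda r: r.element):
            col = {}
            if r.degenerate:
                for slot in PREDICTOR_SLOTS:
                    col[slot] = ""
                col["total_variance"] = "degenerate"
            else:
                for slot in PREDICTOR_SLOTS:
                    if slot in r.table.index:
                        row = r.table.loc[slot]
                        col[slot] = _format_cell(row["share_percent"],
                                                 bool(row["significant"]),
                                                 bool(row["dominant"]),
                                                 row["direction"])
                    else:
                        col[slot] = "-"     # deduplicated slot
                col["total_variance"] = f"{r.total_variance_percent:.2f}"
            data[r.element] = col
        frame = pd.DataFrame(data)
        frame.insert(0, "food_group", group)
        frame.index.name = "predictor"
        frames.append(frame.reset_index())
    return pd.concat(frames, ignore_index=True)
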