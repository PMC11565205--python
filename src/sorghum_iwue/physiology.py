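"""Leaf-level derived quantities.

Intrinsic water-use efficiency (iWUE = A_n / g_s), hydraulic conductances from
the evaporative-flux method, the serial resistance decomposition, transpiration
interpolation from light-response curves, and leaf morphology (LMA, RWC).

Units are fixed at the field's conventions and never converted implicitly:
E in mmol H2O m-2 s-1, A_n in umol CO2 m-2 s-1, g_s in mol H2O m-2 s-1,
water potentials in signed MPa, so conductances come out in
mmol m-2 s-1 MPa-1 and resistances in MPa s m2 mmol-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import DataQualityWarning

__all__ = [
    "compute_iwue",
    "compute_K_leaf",
    "compute_K_plant",
    "decompose_resistances",
    "interpolate_E_at_ppfd",
    "compute_LMA",
    "compute_RWC",
    "LeafDiscSample",
    "derive_traits",
]


def compute_iwue(A_n, g_s):
    """iWUE = A_n / g_s, in umol CO2 mol-1 H2O. Requires g_s > 0."""
    A_n = np.asarray(A_n, dtype=float)
    g_s = np.asarray(g_s, dtype=float)
    if np.any(g_s[np.isfinite(g_s)] <= 0):
        raise ValueError("iWUE undefined: g_s must be > 0")
    out = A_n / g_s
    return float(out) if out.ndim == 0 else out


def _conductance(E, psi_upstream, psi_downstream, label: str):
    """E / (psi_upstream - psi_downstream); reversed or zero gradients yield
    missing values with a warning (field data contain such rows)."""
    E = np.asarray(E, dtype=float)
    dpsi = np.asarray(psi_upstream, dtype=float) - np.asarray(psi_downstream, dtype=float)
    bad = np.isfinite(dpsi) & (dpsi <= 0)
    n_bad = int(np.sum(bad))
    if n_bad:
        warnings.warn(
            f"{label}: {n_bad} nonpositive water-potential gradient(s); "
            "returning missing",
            DataQualityWarning,
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, E / np.where(bad, np.nan, dpsi))
    return float(out) if out.ndim == 0 else out


def compute_K_leaf(E, psi_stem, psi_midday):
    """Leaf hydraulic conductance K_leaf = E / (psi_stem - psi_midday)."""
    return _conductance(E, psi_stem, psi_midday, "K_leaf")


def compute_K_plant(E, psi_predawn, psi_midday):
    """Soil-to-leaf (plant) hydraulic conductance
    K_plant = E / (psi_predawn - psi_midday)."""
    return _conductance(E, psi_predawn, psi_midday, "K_plant")


def decompose_resistances(K_leaf, K_plant):
    """Serial resistance split: R_leaf = 1/K_leaf, R_rest = 1/K_plant - R_leaf.

    A negative R_rest (K_leaf < K_plant) is physically inconsistent for a
    serial pathway; it is returned as-is but flagged with a warning.
    """
    K_leaf = np.asarray(K_leaf, dtype=float)
    K_plant = np.asarray(K_plant, dtype=float)
    if np.any(K_leaf[np.isfinite(K_leaf)] <= 0) or np.any(
        K_plant[np.isfinite(K_plant)] <= 0
    ):
        raise ValueError("conductances must be > 0 to decompose resistances")
    R_leaf = 1.0 / K_leaf
    R_rest = 1.0 / K_plant - R_leaf
    n_neg = int(np.sum(np.isfinite(R_rest) & (R_rest < 0)))
    if n_neg:
        warnings.warn(
            f"{n_neg} negative R_rest value(s): K_leaf < K_plant is inconsistent "
            "with a serial soil-to-leaf pathway",
            DataQualityWarning,
            stacklevel=2,
        )
    if R_leaf.ndim == 0:
        return float(R_leaf), float(R_rest)
    return R_leaf, R_rest


def interpolate_E_at_ppfd(light_response, ppfd, extrapolate: bool = False) -> float:
    """Transpiration at a given light level from a plant's light-response curve.

    Piecewise-linear interpolation over the PPFD-sorted (PPFD, E) points —
    assumption-free and bracketed by the data. Targets outside the measured
    PPFD range are refused unless ``extrapolate`` is set (then the end
    segments are extended linearly).
    """
    pts = sorted((float(p), float(e)) for p, e in light_response)
    if len(pts) < 2:
        raise ValueError("need at least 2 light-response points")
    x = np.array([p for p, _ in pts])
    y = np.array([e for _, e in pts])
    if not extrapolate and not (x[0] <= ppfd <= x[-1]):
        raise ValueError(
            f"PPFD {ppfd:g} outside measured range [{x[0]:g}, {x[-1]:g}] "
            "(enable extrapolation to override)"
        )
    if ppfd < x[0]:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return float(y[0] + slope * (ppfd - x[0]))
    if ppfd > x[-1]:
        slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
        return float(y[-1] + slope * (ppfd - x[-1]))
    return float(np.interp(ppfd, x, y))


@dataclass(frozen=True)
class LeafDiscSample:
    """Fresh, turgid and dry weights (g) of leaf discs of known area (m2)."""

    FW: float
    TW: float
    DW: float
    area: float


def compute_LMA(disc_or_DW, area=None):
    """Leaf mass per area, DW / area, g m-2."""
    if isinstance(disc_or_DW, LeafDiscSample):
        DW, area = disc_or_DW.DW, disc_or_DW.area
    else:
        DW = disc_or_DW
    DW = np.asarray(DW, dtype=float)
    area = np.asarray(area, dtype=float)
    if np.any(area[np.isfinite(area)] <= 0):
        raise ValueError("disc area must be > 0")
    out = DW / area
    return float(out) if out.ndim == 0 else out


def compute_RWC(disc_or_FW, TW=None, DW=None, as_percent: bool = False):
    """Relative water content, (FW - DW) / (TW - DW), fraction (or %)."""
    if isinstance(disc_or_FW, LeafDiscSample):
        FW, TW, DW = disc_or_FW.FW, disc_or_FW.TW, disc_or_FW.DW
    else:
        FW = disc_or_FW
    FW = np.asarray(FW, dtype=float)
    TW = np.asarray(TW, dtype=float)
    DW = np.asarray(DW, dtype=float)
    denom = TW - DW
    if np.any(denom[np.isfinite(denom)] <= 0):
        raise ValueError("RWC undefined: turgid weight must exceed dry weight")
    out = (FW - DW) / denom
    if as_percent:
        out = out * 100.0
    return float(out) if out.ndim == 0 else out


def derive_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns to a replicate- or mean-level table.

    Adds iwue, K_leaf, K_plant, R_leaf, R_rest, LMA and RWC_pct wherever the
    inputs are defined; rows with undefined inputs get missing values.
    """
    out = records.copy()
    gs = out["g_s"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["iwue"] = np.where(gs > 0, out["A_n"] / gs, np.nan)
    out["K_leaf"] = compute_K_leaf(out["E"], out["psi_stem"], out["psi_midday"])
    out["K_plant"] = compute_K_plant(out["E"], out["psi_predawn"], out["psi_midday"])
    with np.errstate(divide="ignore", invalid="ignore"):
        kl = np.asarray(out["K_leaf"], dtype=float)
        kp = np.asarray(out["K_plant"], dtype=float)
        r_leaf = np.where(kl > 0, 1.0 / kl, np.nan)
        out["R_leaf"] = r_leaf
        out["R_rest"] = np.where(kp > 0, 1.0 / kp - r_leaf, np.nan)
        area = np.asarray(out["disc_area"], dtype=float)
        out["LMA"] = np.where(area > 0, out["disc_DW"] / area, np.nan)
        denom = np.asarray(out["disc_TW"] - out["disc_DW"], dtype=float)
        out["RWC_pct"] = np.where(
            denom > 0, 100.0 * (out["disc_FW"] - out["disc_DW"]) / denom, np.nan
        )
    return out
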