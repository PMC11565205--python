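"""Phenotypic-change vectors between watering treatments in A_n–C_i space.

For each genotype the change vector runs from its water-stressed to its
well-watered mean operating point, with deltas signed WW - WS so that a
stress-driven decrease in both A_n and C_i gives positive components. The
angle theta = atan2(dA_n, dC_i) in degrees summarizes how the A_n–C_i
covariation shifted: small theta means C_i fell much more than A_n (capacity
maintained under stomatal closure — the drought-resilient direction), large
theta means A_n collapsed along with C_i. The Euclidean magnitude mixes units
(umol m-2 s-1 vs umol mol-1) exactly as the underlying vector-analysis method
does; a z-scored variant is available for a unit-free reading.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .inference import pearson
from .schema import DataQualityWarning

__all__ = ["change_vector", "change_vectors", "theta_component_association"]


def change_vector(mean_WW: dict, mean_WS: dict) -> dict:
    """Change vector between one genotype's WW and WS means.

    Each mean is a mapping with at least ``A_n`` and ``C_i``. Returns
    delta_A_n, delta_C_i (WW - WS), magnitude and theta (degrees).
    """
    d_an = float(mean_WW["A_n"]) - float(mean_WS["A_n"])
    d_ci = float(mean_WW["C_i"]) - float(mean_WS["C_i"])
    return {
        "delta_A_n": d_an,
        "delta_C_i": d_ci,
        "magnitude": float(np.hypot(d_an, d_ci)),
        "theta": float(np.degrees(np.arctan2(d_an, d_ci))),
    }


def change_vectors(means: pd.DataFrame, standardize: bool = False) -> pd.DataFrame:
    """Per-genotype change vectors from a genotype x treatment means table.

    Genotypes missing either treatment or either trait are skipped with one
    aggregated warning. Rows with negative delta_C_i (C_i higher under WS)
    are flagged, not dropped. With ``standardize`` the deltas are z-scored
    across genotypes (by each axis's SD) before computing theta and
    magnitude, removing the unit mixing.
    """
    wide = means.pivot_table(
        index="genotype_id", columns="treatment", values=["A_n", "C_i"]
    )
    needed = [("A_n", "WW"), ("A_n", "WS"), ("C_i", "WW"), ("C_i", "WS")]
    missing_cols = [c for c in needed if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"means table lacks treatment columns: {missing_cols}")
    complete = wide.dropna(subset=needed)
    n_skipped = len(wide) - len(complete)
    if n_skipped:
        warnings.warn(
            f"{n_skipped} genotype(s) missing A_n/C_i in one treatment; skipped",
            DataQualityWarning,
            stacklevel=2,
        )
    d_an = (complete[("A_n", "WW")] - complete[("A_n", "WS")]).to_numpy(dtype=float)
    d_ci = (complete[("C_i", "WW")] - complete[("C_i", "WS")]).to_numpy(dtype=float)
    if standardize:
        sd_an = np.std(d_an, ddof=1)
        sd_ci = np.std(d_ci, ddof=1)
        if sd_an == 0 or sd_ci == 0:
            raise ValueError("cannot standardize: zero variance in a delta axis")
        d_an_u, d_ci_u = d_an / sd_an, d_ci / sd_ci
    else:
        d_an_u, d_ci_u = d_an, d_ci
    out = pd.DataFrame(
        {
            "genotype_id": complete.index.to_numpy(),
            "delta_A_n": d_an,
            "delta_C_i": d_ci,
            "magnitude": np.hypot(d_an_u, d_ci_u),
            "theta": np.degrees(np.arctan2(d_an_u, d_ci_u)),
            "negative_delta_C_i": d_ci < 0,
        }
    )
    n_neg = int(out["negative_delta_C_i"].sum())
    if n_neg:
        warnings.warn(
            f"{n_neg} genotype(s) with negative delta_C_i (C_i rose under WS)",
            DataQualityWarning,
            stacklevel=2,
        )
    return out


def theta_component_association(
    vectors: pd.DataFrame, partitions: pd.DataFrame
) -> dict:
    """Correlate theta with the WS-WW change of each iWUE component.

    ``partitions`` is a partition table covering both treatments. Returns
    Pearson results for theta vs (delta_iwue_pc(WS) - delta_iwue_pc(WW)) and
    theta vs (delta_iwue_gs(WS) - delta_iwue_gs(WW)), plus the merged table.
    Degenerate (constant) series yield missing correlations.
    """
    comp = partitions.pivot_table(
        index="genotype_id",
        columns="treatment",
        values=["delta_iwue_gs", "delta_iwue_pc"],
    )
    needed = [
        ("delta_iwue_gs", "WW"),
        ("delta_iwue_gs", "WS"),
        ("delta_iwue_pc", "WW"),
        ("delta_iwue_pc", "WS"),
    ]
    comp = comp.dropna(subset=[c for c in needed if c in comp.columns])
    comp.columns = [f"{trait}_{trt}" for trait, trt in comp.columns]
    merged = vectors.set_index("genotype_id").join(comp, how="inner")
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} genotype(s) matched across vectors and "
            "partitions; need >= 3"
        )
    dd_pc = (
        merged["delta_iwue_pc_WS"] - merged["delta_iwue_pc_WW"]
    ).to_numpy(dtype=float)
    dd_gs = (
        merged["delta_iwue_gs_WS"] - merged["delta_iwue_gs_WW"]
    ).to_numpy(dtype=float)
    theta = merged["theta"].to_numpy(dtype=float)
    return {
        "theta_vs_delta_pc": pearson(theta, dd_pc),
        "theta_vs_delta_gs": pearson(theta, dd_gs),
        "n": len(merged),
        "table": merged,
    }
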