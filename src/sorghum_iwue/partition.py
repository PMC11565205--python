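"""Partitioning iWUE into stomatal and photosynthetic-capacity components.

A reference iWUE-vs-g_s curve is fitted across all retained observations of
both treatments. For each genotype x treatment mean, the curve predicts the
iWUE expected from its g_s alone (constant photosynthetic behaviour along the
curve); the deviation of that prediction from the treatment-mean iWUE is the
stomatal component (delta_iwue_gs), and the residual between observed and
predicted iWUE is the non-stomatal, photosynthetic-capacity component
(delta_iwue_pc). By construction

    delta_iwue_gs + delta_iwue_pc = iWUE_obs - treatment mean iWUE

exactly, so the two components tile each genotype's deviation from its
treatment's population mean.

Two curve forms are supported: a two-parameter power law iWUE = a * g_s^b
fitted by least squares on the log-log scale (the default; b < 0 enforces the
declining iWUE-g_s relation), and a constant-assimilation hyperbola
iWUE = A_ref / g_s with A_ref the grand-mean A_n (the power law nests it at
b = -1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import pearson
from .schema import DataQualityWarning

__all__ = [
    "ReferenceCurveModel",
    "ReferenceCurveResults",
    "fit_reference_curve",
    "partition_iwue",
    "treatment_mean_iwue",
    "compare_reference_choices",
]


class CurveFitError(RuntimeError):
    """The fitted reference curve is unusable (e.g. not decreasing in g_s)."""


class ReferenceCurveModel:
    """Monotone-decreasing reference relation between iWUE and g_s.

    Parameters
    ----------
    g_s, iwue : array-like
        Paired observations pooled across treatments (all must have g_s > 0;
        the power form additionally needs iwue > 0).
    form : {"power", "constant_A_hyperbola"}
    """

    def __init__(self, g_s, iwue, form: str = "power", min_n: int = 5):
        g_s = np.asarray(g_s, dtype=float)
        iwue = np.asarray(iwue, dtype=float)
        ok = np.isfinite(g_s) & np.isfinite(iwue) & (g_s > 0)
        if form == "power":
            ok &= iwue > 0
        self.g_s = g_s[ok]
        self.iwue = iwue[ok]
        if len(self.g_s) < min_n:
            raise ValueError(
                f"need at least {min_n} usable (g_s, iWUE) observations"
            )
        if form not in ("power", "constant_A_hyperbola"):
            raise ValueError(f"unknown curve form {form!r}")
        self.form = form

    def fit(self) -> "ReferenceCurveResults":
        domain = (float(self.g_s.min()), float(self.g_s.max()))
        if self.form == "power":
            lx, ly = np.log(self.g_s), np.log(self.iwue)
            b, log_a = np.polyfit(lx, ly, 1)
            if b >= 0:
                raise CurveFitError(
                    f"power-law exponent b = {b:.4g} >= 0: fitted curve is not "
                    "decreasing in g_s; consider the constant_A_hyperbola form"
                )
            resid = ly - (log_a + b * lx)
            ss_tot = float(np.sum((ly - ly.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
            params = {"a": float(np.exp(log_a)), "b": float(b)}
        else:
            a_ref = float(np.mean(self.iwue * self.g_s))  # grand-mean A_n
            pred = a_ref / self.g_s
            ss_tot = float(np.sum((self.iwue - self.iwue.mean()) ** 2))
            r2 = (
                1.0 - float(np.sum((self.iwue - pred) ** 2)) / ss_tot
                if ss_tot > 0
                else np.nan
            )
            params = {"A_ref": a_ref}
        return ReferenceCurveResults(
            form=self.form, params=params, domain=domain, r_squared=r2, n=len(self.g_s)
        )


@dataclass
class ReferenceCurveResults:
    """Fitted reference curve: parameters, fit domain and diagnostics.

    For the power form ``r_squared`` is on the log-log fitting scale; for the
    hyperbola it is on the iWUE scale.
    """

    form: str
    params: dict
    domain: tuple[float, float]
    r_squared: float
    n: int

    def predict(self, g_s, warn_extrapolation: bool = True):
        g_s = np.asarray(g_s, dtype=float)
        outside = np.isfinite(g_s) & ((g_s < self.domain[0]) | (g_s > self.domain[1]))
        if warn_extrapolation and np.any(outside):
            warnings.warn(
                f"{int(outside.sum())} g_s value(s) outside the curve fit domain "
                f"[{self.domain[0]:.4g}, {self.domain[1]:.4g}]; extrapolating",
                DataQualityWarning,
                stacklevel=2,
            )
        if self.form == "power":
            out = self.params["a"] * g_s ** self.params["b"]
        else:
            out = self.params["A_ref"] / g_s
        return float(out) if out.ndim == 0 else out

    def in_domain(self, g_s):
        g_s = np.asarray(g_s, dtype=float)
        out = (g_s >= self.domain[0]) & (g_s <= self.domain[1])
        return bool(out) if out.ndim == 0 else out

    def summary(self) -> str:
        pstr = ", ".join(f"{k} = {v:.6g}" for k, v in self.params.items())
        return (
            f"Reference curve ({self.form}): {pstr}\n"
            f"fit domain g_s in [{self.domain[0]:.4g}, {self.domain[1]:.4g}], "
            f"n = {self.n}, R^2 = {self.r_squared:.4f}"
        )

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "form": self.form,
                "params": self.params,
                "domain": list(self.domain),
                "r_squared": self.r_squared,
                "n": self.n,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def fit_reference_curve(g_s, iwue, form: str = "power") -> ReferenceCurveResults:
    """Convenience wrapper: build and fit a :class:`ReferenceCurveModel`."""
    return ReferenceCurveModel(g_s, iwue, form=form).fit()


def treatment_mean_iwue(means: pd.DataFrame, iwue_col: str = "iwue") -> dict[str, float]:
    """Population-mean iWUE per treatment over retained genotype means."""
    return means.groupby("treatment")[iwue_col].mean().to_dict()


def partition_iwue(
    means: pd.DataFrame,
    curve: ReferenceCurveResults,
    treatment_means: dict[str, float] | None = None,
    gs_col: str = "g_s",
    iwue_col: str = "iwue",
) -> pd.DataFrame:
    """Split each genotype's iWUE deviation into its two components.

    Parameters
    ----------
    means : DataFrame
        Retained genotype x treatment means with g_s and iWUE columns (an
        ``iwue`` column is derived from A_n/g_s if absent).
    curve : ReferenceCurveResults
    treatment_means : dict, optional
        Treatment-mean iWUE; computed from ``means`` when omitted, which
        guarantees the per-treatment zero-mean property of the components.

    Returns a frame with iwue_obs, iwue_calc, treatment_mean_iwue,
    delta_iwue_gs, delta_iwue_pc and an ``extrapolated`` flag for rows whose
    g_s lies outside the curve's fit domain.
    """
    work = means.copy()
    if iwue_col not in work.columns:
        work[iwue_col] = work["A_n"] / work[gs_col]
    work = work.dropna(subset=[gs_col, iwue_col])
    if treatment_means is None:
        treatment_means = treatment_mean_iwue(work, iwue_col)
    gs = work[gs_col].to_numpy(dtype=float)
    iwue_obs = work[iwue_col].to_numpy(dtype=float)
    iwue_calc = curve.predict(gs, warn_extrapolation=False)
    trt_mean = work["treatment"].map(treatment_means).to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "genotype_id": work["genotype_id"].to_numpy(),
            "treatment": work["treatment"].to_numpy(),
            "g_s": gs,
            "iwue_obs": iwue_obs,
            "iwue_calc": iwue_calc,
            "treatment_mean_iwue": trt_mean,
            "delta_iwue_gs": iwue_calc - trt_mean,
            "delta_iwue_pc": iwue_obs - iwue_calc,
            "extrapolated": ~curve.in_domain(gs),
        }
    )
    return out


def compare_reference_choices(
    means: pd.DataFrame,
    curve_global: ReferenceCurveResults,
    curve_reference: ReferenceCurveResults,
    treatment_means: dict[str, float] | None = None,
) -> dict:
    """Agreement between partitions under two reference-curve choices.

    Typically ``curve_global`` is fitted on the whole population and
    ``curve_reference`` on a single reference genotype. Returns the Pearson R
    between component values under the two curves, per component, plus the
    paired table.
    """
    part_a = partition_iwue(means, curve_global, treatment_means=treatment_means)
    part_b = partition_iwue(means, curve_reference, treatment_means=treatment_means)
    merged = part_a.merge(
        part_b[["genotype_id", "treatment", "delta_iwue_gs", "delta_iwue_pc"]],
        on=["genotype_id", "treatment"],
        suffixes=("_global", "_reference"),
    )
    report = {"table": merged}
    for comp in ("delta_iwue_gs", "delta_iwue_pc"):
        res = pearson(merged[f"{comp}_global"], merged[f"{comp}_reference"])
        report[f"r_{comp}"] = res.r
        report[f"p_{comp}"] = res.p
    return report


def fit_genotype_reference_curve(
    records: pd.DataFrame,
    genotype_id: str,
    form: str = "power",
    gs_col: str = "g_s",
    iwue_col: str = "iwue",
) -> ReferenceCurveResults:
    """Reference curve from one genotype's replicate observations (>= 3)."""
    sub = records.loc[records["genotype_id"] == genotype_id].copy()
    if iwue_col not in sub.columns:
        sub[iwue_col] = sub["A_n"] / sub[gs_col]
    sub = sub.dropna(subset=[gs_col, iwue_col])
    if len(sub) < 3:
        raise ValueError(
            f"reference genotype {genotype_id!r} has only {len(sub)} usable "
            "observations (need >= 3)"
        )
    return ReferenceCurveModel(
        sub[gs_col], sub[iwue_col], form=form, min_n=3
    ).fit()
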