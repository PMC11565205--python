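"""Balanced two-way ANOVA, variance components, heritability, GCV/PCV.

The trait summary mirrors the classic quantitative-genetics workflow for a
genotype x treatment trial: mean squares from a two-factor ANOVA with
interaction, variance components under either of two conventions, broad-sense
heritability H_b^2 = sigma_g^2 / sigma_p^2, and genotypic/phenotypic
coefficients of variation (100 * sigma / |mean|).

Two variance-component conventions are offered:

``paper_literal``
    Mean squares taken directly as the components (sigma_g^2 = MS_G,
    sigma_gxt^2 = MS_GxT, sigma_e^2 = MS_E) with the phenotypic variance
    assembled as sigma_g^2 + sigma_gxt^2 / n_treatments +
    sigma_e^2 / n_replicates_std. The replicate count is standardized at 5 by
    default (averaging the nominal 6 replicates over the two treatments down
    to account for genotypes missing in one treatment).
``ems``
    Standard expected-mean-squares estimators for a random genotype effect:
    sigma_e^2 = MS_E, sigma_gxt^2 = (MS_GxT - MS_E)/r,
    sigma_g^2 = (MS_G - MS_GxT)/(r*t), truncated at zero with a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import DataQualityWarning

__all__ = [
    "TwoWayAnova",
    "TwoWayAnovaResults",
    "VarianceComponents",
    "variance_components",
    "heritability",
    "gcv_pcv",
    "fold_change",
    "trait_summary",
    "N_REPLICATES_STD_DEFAULT",
]

N_REPLICATES_STD_DEFAULT = 5


class TwoWayAnova:
    """Two-factor fixed-effects ANOVA with interaction on a long table.

    Parameters
    ----------
    data : DataFrame
        Replicate-level records.
    trait : str
        Response column.
    factors : (str, str)
        Factor columns; defaults to ``("genotype_id", "treatment")``.

    The design must be balanced (equal cell counts, no empty cells); an
    unbalanced table falls back to the unweighted-means analysis (cell means
    scaled by the harmonic mean cell size, residual pooled within cells) with
    a warning.
    """

    def __init__(self, data: pd.DataFrame, trait: str, factors=("genotype_id", "treatment")):
        self.trait = trait
        self.factors = tuple(factors)
        cols = list(self.factors) + [trait]
        self.data = data[cols].dropna(subset=[trait]).copy()
        if self.data.empty:
            raise ValueError(f"no non-missing observations for trait {trait!r}")

    def fit(self) -> "TwoWayAnovaResults":
        a_col, b_col = self.factors
        y = self.data[self.trait].to_numpy(dtype=float)
        a_codes, a_levels = pd.factorize(self.data[a_col], sort=True)
        b_codes, b_levels = pd.factorize(self.data[b_col], sort=True)
        A, B = len(a_levels), len(b_levels)
        if A < 2 or B < 2:
            raise ValueError("each factor needs at least 2 levels")
        counts = np.zeros((A, B), dtype=int)
        np.add.at(counts, (a_codes, b_codes), 1)
        if np.any(counts == 0):
            raise ValueError("empty cells: every factor combination needs data")
        balanced = counts.min() == counts.max()
        sums = np.zeros((A, B))
        np.add.at(sums, (a_codes, b_codes), y)
        cell_means = sums / counts
        r_eff = float(counts[0, 0]) if balanced else float(
            counts.size / np.sum(1.0 / counts)
        )
        if not balanced:
            warnings.warn(
                "unbalanced design: using unweighted-means analysis "
                f"(harmonic mean cell size {r_eff:.3g})",
                DataQualityWarning,
                stacklevel=2,
            )
        if np.ptp(y) == 0:  # exactly constant response: all SS identically 0
            ss_a = ss_b = ss_ab = ss_e = 0.0
        else:
            grand = cell_means.mean()
            a_means = cell_means.mean(axis=1)
            b_means = cell_means.mean(axis=0)
            ss_a = r_eff * B * np.sum((a_means - grand) ** 2)
            ss_b = r_eff * A * np.sum((b_means - grand) ** 2)
            interaction = cell_means - a_means[:, None] - b_means[None, :] + grand
            ss_ab = r_eff * np.sum(interaction**2)
            ss_e = float(np.sum((y - cell_means[a_codes, b_codes]) ** 2))
            # cancellation dust from an exactly-null source is set to 0 so
            # degenerate designs yield exact zero components downstream
            tol = 1e-24 * (ss_a + ss_b + ss_ab + ss_e)
            ss_a, ss_b, ss_ab, ss_e = (
                0.0 if ss < tol else ss for ss in (ss_a, ss_b, ss_ab, ss_e)
            )
        df_a, df_b = A - 1, B - 1
        df_ab = df_a * df_b
        df_e = len(y) - A * B
        rows = []
        ms_e = ss_e / df_e if df_e > 0 else np.nan
        for name, ss, df in (
            (a_col, ss_a, df_a),
            (b_col, ss_b, df_b),
            (f"{a_col}:{b_col}", ss_ab, df_ab),
            ("residual", ss_e, df_e),
        ):
            ms = ss / df if df > 0 else np.nan
            if name == "residual" or not np.isfinite(ms_e) or ms_e <= 0:
                F = p = np.nan
            else:
                F = ms / ms_e
                p = float(stats.f.sf(F, df, df_e))
            rows.append((name, df, ss, ms, F, p))
        table = pd.DataFrame(
            rows, columns=["source", "df", "sum_sq", "mean_sq", "F", "p"]
        ).set_index("source")
        return TwoWayAnovaResults(
            model=self,
            table=table,
            n_levels=(A, B),
            n_per_cell=r_eff,
            balanced=balanced,
            cell_means=pd.DataFrame(cell_means, index=a_levels, columns=b_levels),
        )


@dataclass
class TwoWayAnovaResults:
    """Decomposition table plus design metadata from :class:`TwoWayAnova`."""

    model: TwoWayAnova
    table: pd.DataFrame
    n_levels: tuple[int, int]
    n_per_cell: float
    balanced: bool
    cell_means: pd.DataFrame

    @property
    def anova_table(self) -> pd.DataFrame:
        return self.table

    def mean_squares(self) -> dict[str, float]:
        a_col, b_col = self.model.factors
        return {
            "genotype": float(self.table.loc[a_col, "mean_sq"]),
            "treatment": float(self.table.loc[b_col, "mean_sq"]),
            "interaction": float(self.table.loc[f"{a_col}:{b_col}", "mean_sq"]),
            "residual": float(self.table.loc["residual", "mean_sq"]),
        }

    def variance_components(
        self,
        convention: str = "paper_literal",
        n_replicates_std: int = N_REPLICATES_STD_DEFAULT,
        interaction_divisor: float | None = None,
    ) -> "VarianceComponents":
        ms = self.mean_squares()
        return variance_components(
            ms_genotype=ms["genotype"],
            ms_interaction=ms["interaction"],
            ms_residual=ms["residual"],
            n_treatments=self.n_levels[1],
            n_replicates=self.n_per_cell,
            n_replicates_std=n_replicates_std,
            convention=convention,
            trait=self.model.trait,
            interaction_divisor=interaction_divisor,
        )

    def summary(self) -> str:
        a_col, b_col = self.model.factors
        lines = [
            f"Two-way ANOVA: {self.model.trait} ~ {a_col} * {b_col}",
            f"levels: {self.n_levels[0]} x {self.n_levels[1]}, "
            f"n per cell: {self.n_per_cell:g} "
            f"({'balanced' if self.balanced else 'unweighted-means'})",
            self.table.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


@dataclass
class VarianceComponents:
    """Variance components and the derived genetic-variation statistics."""

    trait: str
    sigma2_g: float
    sigma2_gxt: float
    sigma2_e: float
    sigma2_p: float
    n_treatments: int
    n_replicates_std: float
    convention: str
    truncated: tuple[str, ...] = field(default_factory=tuple)

    @property
    def heritability(self) -> float:
        return heritability(self.sigma2_g, self.sigma2_p)

    def gcv_pcv(self, mean: float) -> tuple[float, float]:
        return gcv_pcv(self.sigma2_g, self.sigma2_p, mean)


def phenotypic_variance(
    sigma2_g: float,
    sigma2_gxt: float,
    sigma2_e: float,
    n_treatments: int,
    n_replicates_std: float,
) -> float:
    """sigma_p^2 = sigma_g^2 + sigma_gxt^2 / t + sigma_e^2 / r_std."""
    return sigma2_g + sigma2_gxt / n_treatments + sigma2_e / n_replicates_std


def variance_components(
    ms_genotype: float,
    ms_interaction: float,
    ms_residual: float,
    n_treatments: int = 2,
    n_replicates: float = 3,
    n_replicates_std: float = N_REPLICATES_STD_DEFAULT,
    convention: str = "paper_literal",
    trait: str = "",
    interaction_divisor: float | None = None,
) -> VarianceComponents:
    """Variance components from ANOVA mean squares under either convention.

    ``interaction_divisor`` overrides the n_treatments divisor applied to the
    interaction component inside sigma_p^2 (exposed because published tables
    are not always reconstructible with the nominal divisor).
    """
    truncated: list[str] = []
    if convention == "paper_literal":
        s2g, s2gxt, s2e = ms_genotype, ms_interaction, ms_residual
    elif convention == "ems":
        r, t = n_replicates, n_treatments
        s2e = ms_residual
        s2gxt = (ms_interaction - ms_residual) / r
        s2g = (ms_genotype - ms_interaction) / (r * t)
        if s2gxt < 0:
            s2gxt = 0.0
            truncated.append("sigma2_gxt")
        if s2g < 0:
            s2g = 0.0
            truncated.append("sigma2_g")
    else:
        raise ValueError(f"unknown convention {convention!r}")
    divisor = n_treatments if interaction_divisor is None else interaction_divisor
    s2p = s2g + s2gxt / divisor + s2e / n_replicates_std
    return VarianceComponents(
        trait=trait,
        sigma2_g=float(s2g),
        sigma2_gxt=float(s2gxt),
        sigma2_e=float(s2e),
        sigma2_p=float(s2p),
        n_treatments=n_treatments,
        n_replicates_std=n_replicates_std,
        convention=convention,
        truncated=tuple(truncated),
    )


def heritability(sigma2_g: float, sigma2_p: float) -> float:
    """Broad-sense heritability H_b^2 = sigma_g^2 / sigma_p^2.

    A degenerate zero phenotypic variance yields 0 (with a warning) rather
    than an error, matching the no-variation limit of a uniform trial.
    """
    if sigma2_p == 0:
        warnings.warn(
            "zero phenotypic variance: H_b^2 reported as 0",
            DataQualityWarning,
            stacklevel=2,
        )
        return 0.0
    if sigma2_p < 0:
        raise ValueError("phenotypic variance must be >= 0")
    return float(sigma2_g / sigma2_p)


def gcv_pcv(sigma2_g: float, sigma2_p: float, mean: float) -> tuple[float, float]:
    """Genotypic and phenotypic coefficients of variation, in percent.

    GCV = 100 * sigma_g / |mean|, PCV = 100 * sigma_p / |mean|. For traits
    whose population mean is near zero (e.g. the iWUE deviation components,
    which are centred by construction) the caller must supply a substitute
    mean on the trait's natural scale, conventionally the iWUE mean.
    """
    if mean == 0:
        raise ValueError(
            "mean is zero: supply a substitute mean (e.g. the iWUE mean for "
            "the centred iWUE components)"
        )
    denom = abs(mean)
    return (
        float(100.0 * np.sqrt(sigma2_g) / denom),
        float(100.0 * np.sqrt(sigma2_p) / denom),
    )


def fold_change(means: pd.DataFrame, trait: str, treatment: str) -> float:
    """Max/min ratio of retained genotype means for one trait and treatment."""
    sub = means.loc[means["treatment"] == treatment, trait].dropna()
    if len(sub) < 2:
        raise ValueError("need at least 2 genotype means for a fold change")
    lo, hi = float(sub.min()), float(sub.max())
    if lo <= 0:
        raise ValueError("fold change undefined: minimum genotype mean <= 0")
    return hi / lo


def trait_summary(
    records: pd.DataFrame,
    means: pd.DataFrame,
    traits: list[str],
    convention: str = "paper_literal",
    n_replicates_std: float = N_REPLICATES_STD_DEFAULT,
    substitute_means: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-trait summary table: mean, fold changes, components, H_b^2, GCV, PCV.

    ``records`` supplies the replicate-level ANOVA; ``means`` (retained
    genotype x treatment means) supplies the fold changes. ``substitute_means``
    maps traits with near-zero means to the denominator used for GCV/PCV.
    """
    substitute_means = substitute_means or {}
    rows = []
    for trait in traits:
        values = records[trait].dropna()
        mean = float(values.mean())
        try:
            res = TwoWayAnova(records, trait).fit()
            vc = res.variance_components(
                convention=convention, n_replicates_std=n_replicates_std
            )
        except ValueError:
            continue
        fc = {}
        for trt in ("WW", "WS"):
            try:
                fc[trt] = fold_change(means, trait, trt)
            except ValueError:
                fc[trt] = np.nan
        denom = substitute_means.get(trait, mean)
        try:
            gcv, pcv = vc.gcv_pcv(denom)
        except ValueError:
            gcv = pcv = np.nan
        rows.append(
            {
                "trait": trait,
                "mean": mean,
                "fold_change_WW": fc["WW"],
                "fold_change_WS": fc["WS"],
                "sigma2_g": vc.sigma2_g,
                "sigma2_gxt": vc.sigma2_gxt,
                "sigma2_e": vc.sigma2_e,
                "sigma2_p": vc.sigma2_p,
                "H_b2": vc.heritability,
                "GCV_pct": gcv,
                "PCV_pct": pcv,
            }
        )
    return pd.DataFrame(rows)
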