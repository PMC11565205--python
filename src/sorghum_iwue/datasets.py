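"""Published reference values for validating the genetic-variation formulas.

Trait summary statistics reported for a glasshouse screen of 89 sorghum NAM
genotypes grown under well-watered (WW) and water-stressed (WS) treatments:
the across-treatment trait mean, per-treatment genotype-mean fold changes,
and ANOVA-derived variance components (genotype, treatment, genotype x
treatment, residual, phenotypic). Feeding the genotypic/phenotypic variances
and means through :func:`sorghum_iwue.quantgen.heritability` and
:func:`sorghum_iwue.quantgen.gcv_pcv` reproduces the published H_b^2, GCV and
PCV columns.

Note: the published phenotypic variances are taken as given — they are not
reconstructible from the published components with the stated replicate
standardization (see docs/methods.md).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_trait_summary", "REFERENCE_AN_RANGE_WW"]

#: extreme WW genotype means for A_n (umol m-2 s-1), min and max
REFERENCE_AN_RANGE_WW = (17.6, 39.3)

_ROWS = [
    # trait, mean, fold WW, fold WS, s2_g, s2_t, s2_gxt, s2_e, s2_p, Hb2, GCV, PCV
    ("A_n", 23.2, 2.23, 6.05, 127.2, 14436.1, 61.6, 61.49, 160.03, 0.79, 48.61, 54.53),
    ("g_s", 0.17, 2.89, 6.35, 0.01, 1.22, 0.0, 0.01, 0.01, 0.75, 58.82, 67.92),
    ("iwue", 148.35, 1.86, 1.78, 963.0, 102434.0, 570.0, 643.17, 1281.63, 0.75, 20.92, 24.13),
    ("C_i", 111.14, 2.83, 6.31, 2214.0, 91498.0, 2170.0, 2011.93, 3339.72, 0.66, 42.34, 52.0),
    ("phi_PSII", 0.39, 1.79, 2.33, 0.01, 0.89, 0.01, 0.01, 0.02, 0.71, 29.24, 34.72),
    ("SPAD", 39.48, 1.92, 3.21, 177.8, 5760.2, 134.4, 78.63, 238.33, 0.75, 33.77, 39.1),
    ("psi_midday", -1.26, 2.25, 2.57, 0.25, 46.64, 0.16, 0.17, 0.34, 0.74, 39.76, 46.07),
    ("psi_predawn", -0.41, 14.28, 14.62, 0.34, 40.87, 0.31, 0.23, 0.49, 0.69, 141.38, 169.92),
    ("leaf_width", 4.54, 2.35, 2.3, 2.16, 4.0, 1.01, 1.41, 2.78, 0.78, 32.37, 36.72),
    ("LMA", 32.01, 2.72, 2.92, 123.76, 64.88, 86.59, 121.6, 176.94, 0.7, 34.75, 41.56),
    ("RWC_pct", 80.52, 1.29, 1.69, 69.28, 2458.99, 111.08, 102.72, 126.85, 0.55, 10.34, 13.99),
    ("biomass", 21.02, 15.59, 15.28, 209.56, 2749.22, 155.35, 138.14, 314.863, 0.67, 68.87, 84.42),
]

_COLUMNS = [
    "trait",
    "mean",
    "fold_change_WW",
    "fold_change_WS",
    "sigma2_g",
    "sigma2_t",
    "sigma2_gxt",
    "sigma2_e",
    "sigma2_p",
    "H_b2",
    "GCV_pct",
    "PCV_pct",
]


def reference_trait_summary() -> pd.DataFrame:
    """The published per-trait summary table, indexed by trait name."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS).set_index("trait")
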