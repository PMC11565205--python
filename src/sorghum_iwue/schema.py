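"""Canonical long-format phenotype schema.

One row per plant replicate under one watering treatment. Columns follow the
field's leaf gas-exchange conventions: A_n in umol CO2 m-2 s-1, g_s in
mol H2O m-2 s-1, C_i in umol mol-1, E in mmol H2O m-2 s-1, water potentials
in (signed, negative) MPa, leaf disc weights in g, disc area in m2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

TREATMENTS = ("WW", "WS")

#: identifying columns required in every table
ID_COLUMNS = ["genotype_id", "treatment", "replicate"]

#: numeric trait columns, in canonical order
TRAIT_COLUMNS = [
    "A_n",
    "g_s",
    "C_i",
    "E",
    "psi_predawn",
    "psi_stem",
    "psi_midday",
    "SPAD",
    "phi_PSII",
    "leaf_width",
    "leaf_length",
    "leaf_thickness",
    "disc_FW",
    "disc_TW",
    "disc_DW",
    "disc_area",
    "biomass",
]

#: optional non-numeric payload (JSON-encoded (PPFD, E) pairs)
OPTIONAL_COLUMNS = ["light_response"]


class SchemaError(ValueError):
    """A required column is missing or an identifying field is invalid."""


class DataQualityWarning(UserWarning):
    """Physiologically implausible but tolerated values (flagged, not fatal)."""


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format record table in place.

    Hard errors: missing identifying columns, unknown treatment labels.
    Soft flags (warnings): psi_predawn < psi_midday (reversed diurnal
    gradient), disc weight ordering DW <= FW <= TW violated, phi_PSII
    outside [0, 1], nonpositive g_s alongside a defined A_n.
    """
    for col in ID_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} is missing")
    bad = set(df["treatment"].dropna().unique()) - set(TREATMENTS)
    if bad:
        raise SchemaError(f"unknown treatment labels: {sorted(bad)!r}; expected WW/WS")

    def _flag(mask: pd.Series, message: str) -> None:
        n = int(np.asarray(mask, dtype=bool).sum())
        if n:
            warnings.warn(f"{n} record(s): {message}", DataQualityWarning, stacklevel=3)

    if {"psi_predawn", "psi_midday"}.issubset(df.columns):
        _flag(df["psi_predawn"] < df["psi_midday"], "psi_predawn below psi_midday")
    if {"disc_FW", "disc_TW", "disc_DW"}.issubset(df.columns):
        _flag(
            (df["disc_DW"] > df["disc_FW"]) | (df["disc_FW"] > df["disc_TW"]),
            "leaf disc weights violate DW <= FW <= TW",
        )
    if "phi_PSII" in df.columns:
        _flag((df["phi_PSII"] < 0) | (df["phi_PSII"] > 1), "phi_PSII outside [0, 1]")
    if {"A_n", "g_s"}.issubset(df.columns):
        _flag(df["A_n"].notna() & (df["g_s"] <= 0), "nonpositive g_s with A_n present")
    return df
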