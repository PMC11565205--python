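"""Reading, writing and aggregating long-format phenotype tables."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .schema import (
    ID_COLUMNS,
    OPTIONAL_COLUMNS,
    TRAIT_COLUMNS,
    DataQualityWarning,
    SchemaError,
    validate_records,
)

__all__ = [
    "read_phenotype_table",
    "write_phenotype_table",
    "aggregate_means",
    "apply_exclusion_filter",
    "GS_FLOOR_DEFAULT",
    "AN_FLOOR_DEFAULT",
]

#: exclusion thresholds for failed water-stressed plants (both must fail)
GS_FLOOR_DEFAULT = 0.02  # mol m-2 s-1
AN_FLOOR_DEFAULT = 2.0  # umol m-2 s-1


def _load_mapping(schema_config) -> dict:
    """Resolve a column mapping: dict, YAML/JSON path, or None (identity)."""
    if schema_config is None:
        return {}
    if isinstance(schema_config, (str, Path)):
        text = Path(schema_config).read_text()
        return yaml.safe_load(text) or {}
    return dict(schema_config)


def read_phenotype_table(path, schema_config=None, delimiter: str = ",") -> pd.DataFrame:
    """Read a replicate-level phenotype CSV into the canonical schema.

    Parameters
    ----------
    path : str or Path
        CSV file, UTF-8, "." decimal.
    schema_config : dict or path, optional
        Mapping from canonical column names to file column names, e.g.
        ``{"A_n": "An", "g_s": "gs"}``. Also accepts a YAML/JSON file.
        Canonical names already present in the file need no entry.
    delimiter : str
        Field separator.

    Returns
    -------
    DataFrame in canonical long format; unparseable numeric cells become
    missing values with a single aggregated warning. Row order is preserved.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=True)
    mapping = _load_mapping(schema_config)
    rename = {file_col: canon for canon, file_col in mapping.items()}
    raw = raw.rename(columns=rename)

    for col in ID_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(
                f"required column {col!r} not found in {path} "
                f"(available: {list(raw.columns)!r})"
            )

    out = pd.DataFrame(index=raw.index)
    out["genotype_id"] = raw["genotype_id"].astype(str)
    out["treatment"] = raw["treatment"].astype(str)
    rep = pd.to_numeric(raw["replicate"], errors="coerce")
    if rep.isna().any():
        raise SchemaError("non-numeric replicate identifiers")
    out["replicate"] = rep.astype(int)

    def _parse_float(value):
        # float() is correctly rounded, unlike the fast csv float path
        try:
            return float(value)
        except (TypeError, ValueError):
            return np.nan

    n_coerced = 0
    for col in TRAIT_COLUMNS:
        if col in raw.columns:
            numeric = raw[col].map(_parse_float).astype(float)
            n_coerced += int((numeric.isna() & raw[col].notna()).sum())
            out[col] = numeric
        else:
            out[col] = np.nan
    for col in OPTIONAL_COLUMNS:
        if col in raw.columns:
            out[col] = raw[col]
    if n_coerced:
        warnings.warn(
            f"{n_coerced} non-numeric cell(s) set to missing while reading {path}",
            DataQualityWarning,
            stacklevel=2,
        )
    return validate_records(out)


def write_phenotype_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write records to CSV at full stored precision (round-trip safe)."""
    df.to_csv(path, sep=delimiter, index=False)


def aggregate_means(records: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Aggregate replicate rows to genotype x treatment means.

    For each trait the mean is the arithmetic mean over non-missing replicate
    values and the standard error is the sample SD / sqrt(n) over those same
    values; the SE is missing when only one replicate is defined. Per-trait
    replicate counts are kept in ``<trait>_n`` columns.
    """
    if traits is None:
        traits = [
            c
            for c in records.columns
            if c not in ID_COLUMNS and pd.api.types.is_numeric_dtype(records[c])
        ]
    grouped = records.groupby(["genotype_id", "treatment"], sort=True)
    frames = {}
    for trait in traits:
        g = grouped[trait]
        n = g.count()
        mean = g.mean()
        sd = g.std(ddof=1)
        se = sd / np.sqrt(n)
        se[n < 2] = np.nan
        frames[trait] = mean
        frames[f"{trait}_se"] = se
        frames[f"{trait}_n"] = n.astype(float)
    means = pd.DataFrame(frames).reset_index()
    means["n_replicates"] = grouped.size().values
    return means


def apply_exclusion_filter(
    means: pd.DataFrame,
    gs_floor: float = GS_FLOOR_DEFAULT,
    an_floor: float = AN_FLOOR_DEFAULT,
    sidecar_path=None,
):
    """Drop genotype x treatment means from plants that failed under stress.

    A mean is excluded iff its g_s mean < ``gs_floor`` AND its A_n mean <
    ``an_floor`` (both thresholds must fail jointly; missing values never
    trigger exclusion). Mirrors the screen's removal of genotypes whose
    stressed plants had essentially shut down gas exchange.

    Returns ``(retained, excluded)``; the excluded frame carries a ``reason``
    column and, if ``sidecar_path`` is given, is also written there as CSV.
    """
    if gs_floor < 0 or an_floor < 0:
        raise ValueError("exclusion thresholds must be >= 0")
    mask = (
        means["g_s"].notna()
        & means["A_n"].notna()
        & (means["g_s"] < gs_floor)
        & (means["A_n"] < an_floor)
    )
    retained = means.loc[~mask].copy()
    excluded = means.loc[mask, ["genotype_id", "treatment", "A_n", "g_s"]].copy()
    excluded["reason"] = [
        f"g_s mean {g:.4g} < {gs_floor:g} and A_n mean {a:.4g} < {an_floor:g}"
        for a, g in zip(excluded["A_n"], excluded["g_s"])
    ]
    if sidecar_path is not None:
        excluded.to_csv(sidecar_path, index=False)
    return retained, excluded


def parse_light_response(cell) -> list[tuple[float, float]] | None:
    """Decode a JSON-encoded list of (PPFD, E) pairs from a table cell."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    pairs = json.loads(cell)
    return [(float(p), float(e)) for p, e in pairs]
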