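"""End-to-end orchestration: simulate/ingest -> derive -> partition ->
vectors -> genetic variation -> haplotype statistics -> correlation report.

Every stage writes a plain CSV/JSON artifact into the output directory and is
individually recomputable from the previous stage's file; identical config
and seed give byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .inference import correlation_matrix, haplotype_anova
from .io import (
    AN_FLOOR_DEFAULT,
    GS_FLOOR_DEFAULT,
    aggregate_means,
    apply_exclusion_filter,
    read_phenotype_table,
    write_phenotype_table,
)
from .partition import ReferenceCurveModel, partition_iwue
from .physiology import derive_traits
from .quantgen import N_REPLICATES_STD_DEFAULT, trait_summary
from .simulate import SimulationConfig, simulate_trial
from .vectors import change_vectors

__all__ = ["PipelineConfig", "run_pipeline"]

SUMMARY_TRAITS = [
    "A_n",
    "g_s",
    "iwue",
    "C_i",
    "phi_PSII",
    "SPAD",
    "psi_midday",
    "psi_predawn",
    "leaf_width",
    "LMA",
    "RWC_pct",
    "biomass",
]

CORRELATION_TRAITS = SUMMARY_TRAITS + ["E", "K_leaf", "K_plant", "R_leaf", "R_rest"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and conventions for one pipeline run."""

    input_path: str | None = None  # replicate-level CSV; None -> simulate
    schema_config: dict | str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int | None = None  # mandatory when simulating
    gs_floor: float = GS_FLOOR_DEFAULT
    an_floor: float = AN_FLOOR_DEFAULT
    curve_form: str = "power"
    convention: str = "paper_literal"
    n_replicates_std: float = N_REPLICATES_STD_DEFAULT
    alpha: float = 0.05
    haplotype_assignments: str | None = None  # CSV path; None -> simulated labels
    out_dir: str = "iwue_out"

    def validate(self) -> "PipelineConfig":
        if self.input_path is None and self.seed is None:
            raise ValueError("seed is mandatory when simulating the input table")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ValueError(f"input file not found: {self.input_path}")
        return self


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return a dict of in-memory artifacts.

    Writes, in order: records.csv (when simulated), derived.csv, means.csv,
    excluded.csv, partition.csv + curve.json, vectors.csv, table3_like.csv,
    table2_like.csv + letters.csv, correlations.csv, and run.json (config
    echo, package version, seed, warning log).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    captured: list[str] = []
    artifacts: dict = {}

    with warnings.catch_warnings(record=True) as wlog:
        warnings.simplefilter("always")

        assignments = None
        if config.input_path is not None:
            records = _stage("ingest")(read_phenotype_table)(
                config.input_path, config.schema_config
            )
            if records.empty:
                raise RuntimeError("pipeline stage 'ingest' failed: empty input table")
        else:
            records, truth = _stage("simulate")(simulate_trial)(
                config.simulation, seed=config.seed
            )
            assignments = truth.haplotypes
            write_phenotype_table(records, out / "records.csv")
            truth.to_sidecar_csv(out / "ground_truth.csv")
            artifacts["truth"] = truth
        if config.haplotype_assignments is not None:
            assignments = pd.read_csv(config.haplotype_assignments)

        derived = _stage("physiology")(derive_traits)(records)
        derived.to_csv(out / "derived.csv", index=False)

        means_all = _stage("aggregate")(aggregate_means)(
            derived, traits=[c for c in CORRELATION_TRAITS if c in derived.columns]
        )
        means, excluded = _stage("exclusion")(apply_exclusion_filter)(
            means_all, config.gs_floor, config.an_floor, sidecar_path=out / "excluded.csv"
        )
        means.to_csv(out / "means.csv", index=False)

        curve = _stage("reference_curve")(
            lambda: ReferenceCurveModel(
                means["g_s"], means["iwue"], form=config.curve_form
            ).fit()
        )()
        curve.to_json(out / "curve.json")
        partition = _stage("partition")(partition_iwue)(means, curve)
        partition.to_csv(out / "partition.csv", index=False)

        vectors = _stage("vectors")(change_vectors)(means)
        vectors.to_csv(out / "vectors.csv", index=False)

        table3 = _stage("quantgen")(trait_summary)(
            derived,
            means,
            [t for t in SUMMARY_TRAITS if t in derived.columns],
            convention=config.convention,
            n_replicates_std=config.n_replicates_std,
        )
        table3.to_csv(out / "table3_like.csv", index=False)

        table2_rows = []
        letter_rows = []
        if assignments is not None:
            for aqp in sorted(assignments["aquaporin_id"].unique()):
                for trait in ("A_n", "g_s", "iwue"):
                    try:
                        res = haplotype_anova(derived, trait, aqp, assignments)
                    except ValueError:
                        continue
                    for source, row in res.table.iterrows():
                        table2_rows.append(
                            {
                                "aquaporin_id": aqp,
                                "trait": trait,
                                "comparison": source,
                                "df": row["df"],
                                "F": row["F"],
                                "p": row["p"],
                            }
                        )
                    letters = res.tukey(alpha=config.alpha)
                    for _, g in letters.groups.iterrows():
                        letter_rows.append(
                            {
                                "aquaporin_id": aqp,
                                "trait": trait,
                                "group": g["group"],
                                "mean": g["mean"],
                                "n": g["n"],
                                "letters": g["letters"],
                            }
                        )
        table2 = pd.DataFrame(table2_rows)
        table2.to_csv(out / "table2_like.csv", index=False)
        letters_df = pd.DataFrame(letter_rows)
        letters_df.to_csv(out / "letters.csv", index=False)

        correlations = _stage("correlations")(correlation_matrix)(
            means, [t for t in CORRELATION_TRAITS if t in means.columns]
        )
        correlations.to_csv(out / "correlations.csv", index=False)

        captured = [str(w.message) for w in wlog]

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "n_records": int(len(records)),
        "n_means_retained": int(len(means)),
        "n_means_excluded": int(len(excluded)),
        "warnings": captured,
    }
    with open(out / "run.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)

    artifacts.update(
        {
            "records": records,
            "derived": derived,
            "means": means,
            "excluded": excluded,
            "curve": curve,
            "partition": partition,
            "vectors": vectors,
            "table3": table3,
            "table2": table2,
            "letters": letters_df,
            "correlations": correlations,
            "run_log": run_log,
        }
    )
    return artifacts


def _config_echo(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["simulation"] = json.loads(config.simulation.to_json())
    return d
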