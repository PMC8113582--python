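"""End-to-end orchestration: simulate -> validate -> assemble -> pac -> dominance.

Every stage is a pure function of its declared input tables; rerunning the
pipeline with the same configuration and seed produces byte-identical outputs
and an identical manifest.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .assembly import (
    build_interaction_matrix,
    build_metaweb,
    mesocosm_herbivore_biomass,
    plant_index_table,
    standardize_herbivore_biomass,
    zero_fill_presence,
)
from .config import PipelineConfig
from .dominance import dominance_ci_table, exotic_biomass_proportion
from .errors import SchemaError
from .pac import compute_pac, pac_table, pac_treatment_summary
from .synthetic import generate_dataset, write_dataset
from .validate import validate_inputs

logger = logging.getLogger("mesoweb")

INPUT_TABLES = ("mesocosms.csv", "plant_species.csv", "herbivore_species.csv",
                "plants.csv", "surveys.csv", "damage.csv")


def load_tables(indir: str | Path) -> dict[str, pd.DataFrame]:
    indir = Path(indir)
    return {name: pd.read_csv(indir / name) for name in INPUT_TABLES}


def simulate_stage(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    data = generate_dataset(config.generator)
    write_dataset(data["design"], data["surveys"], data["damage"], data["plants"],
                  config.generator, outdir)
    logger.info("simulated %d mesocosms, %d survey records",
                len(data["design"].mesocosms), len(data["surveys"]))
    return {
        "mesocosms.csv": len(data["design"].mesocosms),
        "plants.csv": len(data["plants"]),
        "surveys.csv": len(data["surveys"]),
        "damage.csv": len(data["damage"]),
    }


def validate_stage(indir: Path):
    report = validate_inputs(indir)
    if not report.passed:
        raise SchemaError("input validation failed:\n" + report.summary())
    logger.info("input validation passed")
    return report


def build_matrices(tables: dict[str, pd.DataFrame],
                   std_biomass: pd.DataFrame) -> dict[str, object]:
    """One interaction matrix per mesocosm, columns spanning the full pool."""
    herbivores = sorted(tables["herbivore_species.csv"]["species"])
    matrices = {}
    for meso_id, grp in tables["plants.csv"].groupby("mesocosm_id"):
        matrices[meso_id] = build_interaction_matrix(
            std_biomass, meso_id, grp["plant_id"], herbivores)
    return matrices


def assemble_stage(tables: dict[str, pd.DataFrame], config: PipelineConfig,
                   outdir: Path) -> dict[str, int]:
    surveys = tables["surveys.csv"]
    plants = tables["plants.csv"]
    herb_pool = tables["herbivore_species.csv"]

    std = standardize_herbivore_biomass(surveys, herb_pool, plants)
    matrices = build_matrices(tables, std)
    metaweb = build_metaweb(std, plants, herb_pool)
    zero_filled = zero_fill_presence(std, metaweb, plants)
    indices = plant_index_table(std, tables["damage.csv"], plants, matrices)

    n_surveys = int(plants["n_surveys_observed"].max()) if len(plants) else None
    meso_biomass = mesocosm_herbivore_biomass(
        surveys, herb_pool,
        per_survey=config.normalize_mesocosm_per_survey,
        n_surveys=n_surveys).rename("herbivore_biomass_g").reset_index()

    outputs = {
        "edges.csv": std.rename(columns={"biomass_g": "biomass_g"}),
        "metaweb.csv": metaweb.matrix.reset_index(names="species"),
        "zero_filled_presence.csv": zero_filled,
        "plant_indices.csv": indices,
        "mesocosm_herbivore_biomass.csv": meso_biomass,
    }
    counts = {}
    for name, df in outputs.items():
        df.to_csv(outdir / name, index=False)
        counts[name] = len(df)
    logger.info("assembled %d mesocosm networks (%d realised edges)",
                len(matrices), len(std))
    counts["n_networks"] = len(matrices)
    return counts


def pac_stage(tables: dict[str, pd.DataFrame], config: PipelineConfig,
              outdir: Path) -> dict[str, int]:
    surveys = tables["surveys.csv"]
    plants = tables["plants.csv"]
    herb_pool = tables["herbivore_species.csv"]
    std = standardize_herbivore_biomass(surveys, herb_pool, plants)
    matrices = build_matrices(tables, std)
    results = [compute_pac(m, direction=config.pac_direction)
               for _, m in sorted(matrices.items())]
    pac = pac_table(results, plants)
    pac.to_csv(outdir / "pac.csv", index=False)
    counts = {"pac.csv": len(pac)}

    summary = pac_treatment_summary(pac, tables["mesocosms.csv"])
    summary.to_csv(outdir / "pac_summary.csv", index=False)
    counts["pac_summary.csv"] = len(summary)

    if config.write_d_matrices:
        d_long = pd.concat([r.d_long() for r in results], ignore_index=True)
        d_long.to_csv(outdir / "pac_d_matrices.csv", index=False)
        counts["pac_d_matrices.csv"] = len(d_long)
    return counts


def dominance_stage(tables: dict[str, pd.DataFrame], config: PipelineConfig,
                    outdir: Path) -> dict[str, int]:
    props = exotic_biomass_proportion(tables["plants.csv"],
                                      partition=config.biomass_partition)
    table = dominance_ci_table(props, tables["mesocosms.csv"],
                               method=config.ci_method)
    table.to_csv(outdir / "dominance.csv", index=False)
    return {"dominance.csv": len(table)}


def run_pipeline(config: PipelineConfig,
                 indir: str | Path | None = None) -> dict:
    """Run all stages and write a manifest.

    If ``indir`` is None the synthetic generator provides the inputs (written
    to the output directory); otherwise the six input CSVs are read from
    ``indir`` and only the analysis stages run.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    counts: dict[str, int] = {}
    if indir is None:
        counts.update(simulate_stage(config, outdir))
        indir = outdir
    indir = Path(indir)
    validate_stage(indir)
    tables = load_tables(indir)
    counts.update(assemble_stage(tables, config, outdir))
    counts.update(pac_stage(tables, config, outdir))
    counts.update(dominance_stage(tables, config, outdir))

    manifest = {
        "software": "mesoweb",
        "version": __version__,
        "seed": config.generator.seed,
        "config_sha256": config.config_hash(),
        "flags": {
            "pac_direction": config.pac_direction,
            "normalize_mesocosm_per_survey": config.normalize_mesocosm_per_survey,
            "ci_method": config.ci_method,
            "biomass_partition": config.biomass_partition,
        },
        "row_counts": counts,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
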