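"""Schema and referential-integrity validation for the pipeline's CSV inputs.

CSV dialect: UTF-8, comma-separated, header row required, "." decimal, empty
string = missing.  Each file is checked for required columns, value domains
and cross-file referential integrity; the report lists the first 10
violations per file with row indices (0-based data rows).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

MAX_VIOLATIONS = 10

PROVENANCES = {"native", "exotic"}
FUNCTIONAL_GROUPS = {"herbaceous", "woody"}
GUILDS = {"leaf_chewer", "root_chewer", "sucker", "miner"}
ORIGINS = {"added", "self_colonised"}
HERBIVORE_TREATMENTS = {"plus_H", "minus_H"}
SOIL_TREATMENTS = {"home", "away"}

REQUIRED_COLUMNS = {
    "mesocosms.csv": ["mesocosm_id", "community_id", "herbivore_treatment",
                      "soil_treatment", "replicate", "prop_exotic_planted",
                      "prop_woody_planted"],
    "plant_species.csv": ["species", "provenance", "functional_group"],
    "herbivore_species.csv": ["species", "provenance", "mean_dry_mass_g",
                              "guild", "origin"],
    "plants.csv": ["plant_id", "mesocosm_id", "species", "provenance",
                   "functional_group", "alive", "aboveground_biomass_g",
                   "belowground_biomass_g", "n_surveys_observed"],
    "surveys.csv": ["mesocosm_id", "survey_index", "plant_id",
                    "herbivore_species", "count"],
    "damage.csv": ["mesocosm_id", "survey_index", "plant_id", "category"],
}


@dataclass
class FileReport:
    name: str
    n_rows: int = 0
    violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def add(self, message: str) -> None:
        if len(self.violations) < MAX_VIOLATIONS:
            self.violations.append(message)


@dataclass
class ValidationReport:
    files: dict[str, FileReport] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(f.passed for f in self.files.values())

    def summary(self) -> str:
        lines = []
        for name, rep in self.files.items():
            status = "PASS" if rep.passed else "FAIL"
            lines.append(f"{name}: {status} ({rep.n_rows} rows)")
            for v in rep.violations:
                lines.append(f"  - {v}")
        return "\n".join(lines)


def _check_domain(df: pd.DataFrame, col: str, allowed: set, rep: FileReport) -> None:
    bad = ~df[col].isin(allowed)
    for idx in df.index[bad][:MAX_VIOLATIONS]:
        rep.add(f"row {idx}, column {col}: invalid value {df.loc[idx, col]!r} "
                f"(allowed: {sorted(allowed)})")


def _check_numeric(df: pd.DataFrame, col: str, rep: FileReport,
                   minimum=None, integer=False) -> None:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    for idx in df.index[bad][:MAX_VIOLATIONS]:
        rep.add(f"row {idx}, column {col}: not numeric ({df.loc[idx, col]!r})")
    if minimum is not None:
        low = vals < minimum
        for idx in df.index[low][:MAX_VIOLATIONS]:
            rep.add(f"row {idx}, column {col}: value {vals.loc[idx]} < {minimum}")
    if integer:
        frac = vals.dropna() % 1 != 0
        for idx in frac.index[frac][:MAX_VIOLATIONS]:
            rep.add(f"row {idx}, column {col}: not an integer ({vals.loc[idx]})")


def _check_reference(df: pd.DataFrame, col: str, valid: set, rep: FileReport,
                     ref_name: str) -> None:
    bad = ~df[col].isin(valid)
    for idx in df.index[bad][:MAX_VIOLATIONS]:
        rep.add(f"row {idx}, column {col}: {df.loc[idx, col]!r} not found in {ref_name}")


def validate_inputs(indir: str | Path) -> ValidationReport:
    """Validate the six CSV tables in a directory; returns a per-file report."""
    indir = Path(indir)
    report = ValidationReport()
    frames: dict[str, pd.DataFrame] = {}

    for name, required in REQUIRED_COLUMNS.items():
        rep = FileReport(name)
        report.files[name] = rep
        path = indir / name
        if not path.exists():
            rep.add("file is missing")
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # unreadable file -> I/O style failure
            rep.add(f"unreadable: {exc}")
            continue
        rep.n_rows = len(df)
        missing = [c for c in required if c not in df.columns]
        if missing:
            rep.add(f"missing required columns: {missing}")
            continue
        frames[name] = df

    # per-file domain checks
    if "mesocosms.csv" in frames:
        df, rep = frames["mesocosms.csv"], report.files["mesocosms.csv"]
        _check_domain(df, "herbivore_treatment", HERBIVORE_TREATMENTS, rep)
        _check_domain(df, "soil_treatment", SOIL_TREATMENTS, rep)
        _check_numeric(df, "replicate", rep, minimum=1, integer=True)
        _check_numeric(df, "prop_exotic_planted", rep, minimum=0)
        _check_numeric(df, "prop_woody_planted", rep, minimum=0)
        dup = df["mesocosm_id"].duplicated()
        for idx in df.index[dup][:MAX_VIOLATIONS]:
            rep.add(f"row {idx}: duplicate mesocosm_id {df.loc[idx, 'mesocosm_id']!r}")

    if "plant_species.csv" in frames:
        df, rep = frames["plant_species.csv"], report.files["plant_species.csv"]
        _check_domain(df, "provenance", PROVENANCES, rep)
        _check_domain(df, "functional_group", FUNCTIONAL_GROUPS, rep)

    if "herbivore_species.csv" in frames:
        df, rep = frames["herbivore_species.csv"], report.files["herbivore_species.csv"]
        _check_domain(df, "provenance", PROVENANCES, rep)
        _check_domain(df, "guild", GUILDS, rep)
        _check_domain(df, "origin", ORIGINS, rep)
        _check_numeric(df, "mean_dry_mass_g", rep)
        nonpos = pd.to_numeric(df["mean_dry_mass_g"], errors="coerce") <= 0
        for idx in df.index[nonpos][:MAX_VIOLATIONS]:
            rep.add(f"row {idx}: species {df.loc[idx, 'species']!r} has "
                    f"non-positive mean_dry_mass_g")

    if "plants.csv" in frames:
        df, rep = frames["plants.csv"], report.files["plants.csv"]
        _check_domain(df, "provenance", PROVENANCES, rep)
        _check_domain(df, "functional_group", FUNCTIONAL_GROUPS, rep)
        _check_numeric(df, "aboveground_biomass_g", rep, minimum=0)
        _check_numeric(df, "belowground_biomass_g", rep, minimum=0)
        _check_numeric(df, "n_surveys_observed", rep, minimum=1, integer=True)
        dup = df["plant_id"].duplicated()
        for idx in df.index[dup][:MAX_VIOLATIONS]:
            rep.add(f"row {idx}: duplicate plant_id {df.loc[idx, 'plant_id']!r}")

    if "surveys.csv" in frames:
        df, rep = frames["surveys.csv"], report.files["surveys.csv"]
        _check_numeric(df, "survey_index", rep, minimum=1, integer=True)
        _check_numeric(df, "count", rep, minimum=0, integer=True)

    if "damage.csv" in frames:
        df, rep = frames["damage.csv"], report.files["damage.csv"]
        _check_numeric(df, "survey_index", rep, minimum=1, integer=True)
        cats = pd.to_numeric(df["category"], errors="coerce")
        bad = ~cats.isin(range(6))
        for idx in df.index[bad][:MAX_VIOLATIONS]:
            rep.add(f"row {idx}, column category: {df.loc[idx, 'category']!r} "
                    "outside 0-5")

    # referential integrity
    meso_ids = set(frames["mesocosms.csv"]["mesocosm_id"]) if "mesocosms.csv" in frames else set()
    plant_ids = set(frames["plants.csv"]["plant_id"]) if "plants.csv" in frames else set()
    plant_sp = set(frames["plant_species.csv"]["species"]) if "plant_species.csv" in frames else set()
    herb_sp = set(frames["herbivore_species.csv"]["species"]) if "herbivore_species.csv" in frames else set()

    if "plants.csv" in frames and meso_ids:
        _check_reference(frames["plants.csv"], "mesocosm_id", meso_ids,
                         report.files["plants.csv"], "mesocosms.csv")
    if "plants.csv" in frames and plant_sp:
        _check_reference(frames["plants.csv"], "species", plant_sp,
                         report.files["plants.csv"], "plant_species.csv")
    if "surveys.csv" in frames:
        rep = report.files["surveys.csv"]
        if meso_ids:
            _check_reference(frames["surveys.csv"], "mesocosm_id", meso_ids, rep,
                             "mesocosms.csv")
        if plant_ids:
            _check_reference(frames["surveys.csv"], "plant_id", plant_ids, rep,
                             "plants.csv")
        if herb_sp:
            _check_reference(frames["surveys.csv"], "herbivore_species", herb_sp, rep,
                             "herbivore_species.csv")
    if "damage.csv" in frames:
        rep = report.files["damage.csv"]
        if meso_ids:
            _check_reference(frames["damage.csv"], "mesocosm_id", meso_ids, rep,
                             "mesocosms.csv")
        if plant_ids:
            _check_reference(frames["damage.csv"], "plant_id", plant_ids, rep,
                             "plants.csv")
    return report
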