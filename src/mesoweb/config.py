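"""Generator and pipeline configuration objects, with YAML/JSON round-tripping."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .errors import ConfigurationError

#: counts of exotic members (out of 8) cycled across communities; the default
#: 20-community design is the full 5 x 4 factorial with the woody counts below,
#: which makes the two planted gradients exactly orthogonal.
DEFAULT_EXOTIC_COUNTS = (0, 2, 4, 6, 8)
DEFAULT_WOODY_COUNTS = (0, 1, 3, 5)

DEFAULT_DAMAGE_PROBS = {
    # Damage-category draw weights (categories 0..5). Exotics skew higher.
    "native": (0.62, 0.22, 0.10, 0.04, 0.015, 0.005),
    "exotic": (0.45, 0.27, 0.16, 0.08, 0.03, 0.01),
}

DEFAULT_PLANT_GROWTH = {
    # lognormal (location, scale) of total plant biomass in grams
    "native": (1.6, 0.7),
    "exotic": (3.0, 0.7),
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic mesocosm experiment generator.

    Defaults reproduce the full design (20 communities x 2 herbivore x 2 soil
    treatments x 2 replicates = 160 mesocosms; 39 plant and 20 herbivore
    species; 8 surveys).  Effect-size defaults are free generator parameters
    chosen so the simulated effects have realistic magnitude; they are
    recoverable by the downstream pipeline (see ``mesoweb.recovery``).
    """

    seed: int = 0

    # --- design structure ---
    n_communities: int = 20
    community_size: int = 8
    replicates: int = 2
    herbivore_treatments: tuple[str, ...] = ("plus_H", "minus_H")
    soil_treatments: tuple[str, ...] = ("home", "away")
    n_native_plants: int = 19
    n_exotic_plants: int = 20
    n_woody_native: int = 6
    n_woody_exotic: int = 6
    n_native_herbivores: int = 7
    n_exotic_herbivores: int = 13
    n_added_herbivores: int = 13  # remainder of the pool is self-colonised
    community_exotic_counts: tuple[int, ...] | None = None
    community_woody_counts: tuple[int, ...] | None = None
    host_range_fraction: tuple[float, float] = (0.3, 0.8)

    # --- survey process ---
    n_surveys: int = 8
    base_presence_prob: float = 0.12
    exotic_interaction_odds_multiplier: float = 2.0
    exotic_biomass_multiplier: float = 1.72
    minus_H_presence_retention: float = 0.21
    exotic_herbivore_prop_exotic_slope: float = 1.0
    mean_count_given_presence: float = 3.0
    count_dispersion: float = 1.5

    # --- damage and harvest ---
    damage_category_probabilities: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_DAMAGE_PROBS))
    minus_H_damage_retention: float = 0.76
    herbivory_biomass_penalty_exotic: float = 0.31
    plant_growth: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_PLANT_GROWTH))
    aboveground_beta: tuple[float, float] = (6.0, 4.0)
    plant_death_prob: float = 0.05
    soil_home_biomass_multiplier: float = 1.0  # default: soil treatment is a pure label

    # --- herbivore body mass draw ---
    herbivore_mass_lognormal: tuple[float, float] = (-3.5, 0.8)

    def __post_init__(self):
        self.herbivore_treatments = tuple(self.herbivore_treatments)
        self.soil_treatments = tuple(self.soil_treatments)
        if self.community_exotic_counts is not None:
            self.community_exotic_counts = tuple(self.community_exotic_counts)
        if self.community_woody_counts is not None:
            self.community_woody_counts = tuple(self.community_woody_counts)
        self.validate()

    # counts of exotic / woody members for each community, after defaulting
    def exotic_counts(self) -> tuple[int, ...]:
        if self.community_exotic_counts is not None:
            return tuple(self.community_exotic_counts[i % len(self.community_exotic_counts)]
                         for i in range(self.n_communities))
        return tuple(DEFAULT_EXOTIC_COUNTS[i % len(DEFAULT_EXOTIC_COUNTS)]
                     for i in range(self.n_communities))

    def woody_counts(self) -> tuple[int, ...]:
        if self.community_woody_counts is not None:
            return tuple(self.community_woody_counts[i % len(self.community_woody_counts)]
                         for i in range(self.n_communities))
        # vary the woody count on the slow axis so it is balanced within each
        # exotic level (orthogonal gradients)
        k = len(DEFAULT_EXOTIC_COUNTS)
        return tuple(DEFAULT_WOODY_COUNTS[(i // k) % len(DEFAULT_WOODY_COUNTS)]
                     for i in range(self.n_communities))

    def validate(self) -> None:
        def _chk(cond: bool, msg: str) -> None:
            if not cond:
                raise ConfigurationError(msg)

        _chk(self.n_communities >= 1, "n_communities must be >= 1")
        _chk(self.community_size >= 1, "community_size must be >= 1")
        _chk(self.replicates >= 1, "replicates must be >= 1")
        _chk(len(self.herbivore_treatments) >= 1, "need >= 1 herbivore treatment")
        _chk(len(self.soil_treatments) >= 1, "need >= 1 soil treatment")
        _chk(self.n_surveys >= 1, "n_surveys must be >= 1")
        _chk(0.0 <= self.base_presence_prob <= 1.0,
             "base_presence_prob must be in [0, 1]")
        _chk(self.exotic_interaction_odds_multiplier > 0,
             "exotic_interaction_odds_multiplier must be > 0")
        _chk(self.exotic_biomass_multiplier > 0,
             "exotic_biomass_multiplier must be > 0")
        _chk(0.0 <= self.minus_H_presence_retention <= 1.0,
             "minus_H_presence_retention must be in [0, 1]")
        _chk(0.0 <= self.minus_H_damage_retention <= 1.0,
             "minus_H_damage_retention must be in [0, 1]")
        _chk(0.0 <= self.herbivory_biomass_penalty_exotic <= 1.0,
             "herbivory_biomass_penalty_exotic must be in [0, 1]")
        _chk(0.0 <= self.plant_death_prob <= 1.0,
             "plant_death_prob must be in [0, 1]")
        _chk(self.mean_count_given_presence >= 1.0,
             "mean_count_given_presence must be >= 1 (counts are positive)")
        _chk(self.count_dispersion > 0, "count_dispersion must be > 0")
        _chk(self.soil_home_biomass_multiplier > 0,
             "soil_home_biomass_multiplier must be > 0")
        lo, hi = self.host_range_fraction
        _chk(0.0 < lo <= hi <= 1.0, "host_range_fraction must satisfy 0 < lo <= hi <= 1")
        _chk(self.n_native_plants + self.n_exotic_plants >= self.community_size,
             "plant pool smaller than community size")
        _chk(self.n_woody_native <= self.n_native_plants,
             "n_woody_native exceeds native pool")
        _chk(self.n_woody_exotic <= self.n_exotic_plants,
             "n_woody_exotic exceeds exotic pool")
        _chk(0 <= self.n_added_herbivores
             <= self.n_native_herbivores + self.n_exotic_herbivores,
             "n_added_herbivores exceeds herbivore pool")
        for prov, probs in self.damage_category_probabilities.items():
            _chk(len(probs) == 6, f"damage probabilities for {prov} must have 6 entries")
            _chk(all(p >= 0 for p in probs) and abs(sum(probs) - 1.0) < 1e-9,
                 f"damage probabilities for {prov} must be a distribution")
        for e in self.exotic_counts():
            _chk(0 <= e <= self.community_size,
                 f"community exotic count {e} outside [0, {self.community_size}]")
            _chk(e <= self.n_exotic_plants, f"exotic count {e} exceeds exotic pool")
            _chk(self.community_size - e <= self.n_native_plants,
                 f"native count {self.community_size - e} exceeds native pool")
        for w in self.woody_counts():
            _chk(0 <= w <= self.community_size,
                 f"community woody count {w} outside [0, {self.community_size}]")
            _chk(w <= self.n_woody_native + self.n_woody_exotic,
                 f"woody count {w} exceeds woody pool: cannot place communities "
                 "on both gradients")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["damage_category_probabilities"] = {
            k: list(v) for k, v in self.damage_category_probabilities.items()}
        d["plant_growth"] = {k: list(v) for k, v in self.plant_growth.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**d)


PAC_DIRECTIONS = ("mueller", "swapped")
CI_METHODS = ("t", "bootstrap")
BIOMASS_PARTITIONS = ("total", "aboveground")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (generation + analysis flags)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    outdir: str = "mesoweb_out"
    pac_direction: str = "mueller"
    normalize_mesocosm_per_survey: bool = False
    ci_method: str = "t"
    biomass_partition: str = "total"
    write_d_matrices: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.pac_direction not in PAC_DIRECTIONS:
            raise ConfigurationError(
                f"pac_direction must be one of {PAC_DIRECTIONS}, got {self.pac_direction!r}")
        if self.ci_method not in CI_METHODS:
            raise ConfigurationError(
                f"ci_method must be one of {CI_METHODS}, got {self.ci_method!r}")
        if self.biomass_partition not in BIOMASS_PARTITIONS:
            raise ConfigurationError(
                f"biomass_partition must be one of {BIOMASS_PARTITIONS}, "
                f"got {self.biomass_partition!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(generator=GeneratorConfig.from_dict(gen), **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            if path.suffix.lower() in (".yaml", ".yml"):
                data = yaml.safe_load(fh) or {}
            else:
                data = json.load(fh)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (paths/logging excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()
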