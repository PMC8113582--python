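"""Core domain types: species pools, designs, interaction matrices and results."""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd


class Provenance(str, Enum):
    NATIVE = "native"
    EXOTIC = "exotic"


class FunctionalGroup(str, Enum):
    HERBACEOUS = "herbaceous"
    WOODY = "woody"


class Guild(str, Enum):
    LEAF_CHEWER = "leaf_chewer"
    ROOT_CHEWER = "root_chewer"
    SUCKER = "sucker"
    MINER = "miner"


class Origin(str, Enum):
    ADDED = "added"
    SELF_COLONISED = "self_colonised"


class HerbivoreTreatment(str, Enum):
    PLUS_H = "plus_H"
    MINUS_H = "minus_H"


class SoilTreatment(str, Enum):
    HOME = "home"
    AWAY = "away"


@dataclass(frozen=True)
class PlantSpecies:
    species_id: str
    provenance: Provenance
    functional_group: FunctionalGroup


@dataclass(frozen=True)
class HerbivoreSpecies:
    species_id: str
    provenance: Provenance
    mean_dry_mass: float  # grams per individual
    guild: Guild
    origin: Origin
    fundamental_hosts: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.mean_dry_mass <= 0:
            raise ValueError(
                f"mean_dry_mass must be > 0 for {self.species_id}, "
                f"got {self.mean_dry_mass}")


@dataclass(frozen=True)
class CommunityDesign:
    """A unique plant community: an ordered set of member species."""

    community_id: int
    members: tuple[str, ...]
    prop_exotic_planted: float
    prop_woody_planted: float

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"community {self.community_id} has duplicate members")


@dataclass(frozen=True)
class MesocosmDesign:
    mesocosm_id: str
    community_id: int
    herbivore_treatment: HerbivoreTreatment
    soil_treatment: SoilTreatment
    replicate: int


@dataclass
class ExperimentDesign:
    """The full factorial design: species pools, communities and mesocosms."""

    plant_pool: list[PlantSpecies]
    herbivore_pool: list[HerbivoreSpecies]
    communities: list[CommunityDesign]
    mesocosms: list[MesocosmDesign]

    def __post_init__(self):
        self._communities_by_id = {c.community_id: c for c in self.communities}
        self._plants_by_id = {p.species_id: p for p in self.plant_pool}
        self._herbivores_by_id = {h.species_id: h for h in self.herbivore_pool}

    def community(self, community_id: int) -> CommunityDesign:
        return self._communities_by_id[community_id]

    def plant_species(self, species_id: str) -> PlantSpecies:
        return self._plants_by_id[species_id]

    def herbivore_species(self, species_id: str) -> HerbivoreSpecies:
        return self._herbivores_by_id[species_id]

    @staticmethod
    def plant_id(mesocosm_id: str, species_id: str) -> str:
        """Stable identifier for the individual of `species_id` in a mesocosm."""
        return f"{mesocosm_id}:{species_id}"

    def plant_individuals(self) -> pd.DataFrame:
        """One row per plant individual across all mesocosms."""
        rows = []
        for m in self.mesocosms:
            comm = self.community(m.community_id)
            for sp in comm.members:
                attrs = self.plant_species(sp)
                rows.append({
                    "plant_id": self.plant_id(m.mesocosm_id, sp),
                    "mesocosm_id": m.mesocosm_id,
                    "species": sp,
                    "provenance": attrs.provenance.value,
                    "functional_group": attrs.functional_group.value,
                })
        return pd.DataFrame(rows)

    def mesocosm_table(self) -> pd.DataFrame:
        rows = []
        for m in self.mesocosms:
            comm = self.community(m.community_id)
            rows.append({
                "mesocosm_id": m.mesocosm_id,
                "community_id": m.community_id,
                "herbivore_treatment": m.herbivore_treatment.value,
                "soil_treatment": m.soil_treatment.value,
                "replicate": m.replicate,
                "prop_exotic_planted": comm.prop_exotic_planted,
                "prop_woody_planted": comm.prop_woody_planted,
            })
        return pd.DataFrame(rows)

    def plant_species_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "species": p.species_id,
            "provenance": p.provenance.value,
            "functional_group": p.functional_group.value,
        } for p in self.plant_pool])

    def herbivore_species_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "species": h.species_id,
            "provenance": h.provenance.value,
            "mean_dry_mass_g": h.mean_dry_mass,
            "guild": h.guild.value,
            "origin": h.origin.value,
        } for h in self.herbivore_pool])


@dataclass
class InteractionMatrix:
    """Per-mesocosm plants x herbivores matrix of standardized herbivore biomass (g).

    Rows index plant individuals, columns herbivore species; entries are the
    per-survey-standardized dry biomass of each herbivore on each plant.
    """

    mesocosm_id: str
    plants: list[str]
    herbivores: list[str]
    alpha: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (len(self.plants), len(self.herbivores)):
            raise ValueError(
                f"alpha shape {self.alpha.shape} does not match index lists "
                f"({len(self.plants)} plants, {len(self.herbivores)} herbivores)")
        if np.any(self.alpha < 0):
            raise ValueError("interaction strengths must be non-negative")

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_herbivores(self) -> int:
        return len(self.herbivores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.alpha, index=self.plants, columns=self.herbivores)


@dataclass
class MetaWeb:
    """Experiment-wide binary plant-species x herbivore-species web.

    An entry is 1 iff the pair was realised in at least one mesocosm; the row
    set defines each herbivore's fundamental host range for zero-filling.
    """

    matrix: pd.DataFrame  # index: plant species, columns: herbivore species, values 0/1
    plant_provenance: dict[str, str] = field(default_factory=dict)
    herbivore_provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        vals = self.matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("metaweb entries must be 0/1")

    def hosts_of(self, herbivore: str) -> list[str]:
        col = self.matrix[herbivore]
        return list(col.index[col == 1])

    @property
    def n_edges(self) -> int:
        return int(self.matrix.to_numpy().sum())


@dataclass
class PACResult:
    """Pairwise and aggregated potential for apparent competition in one mesocosm."""

    mesocosm_id: str
    plants: list[str]
    d: np.ndarray                 # d[i, j]: share of pressure on i attributable to j
    pac_exerted: np.ndarray       # per plant, biomass-weighted
    pac_received: np.ndarray
    focal_biomass: np.ndarray     # B_i, total herbivore biomass on plant i (g)
    other_biomass: np.ndarray     # B_-i, herbivore biomass on the rest of the community

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mesocosm_id": self.mesocosm_id,
            "plant_id": self.plants,
            "pac_exerted": self.pac_exerted,
            "pac_received": self.pac_received,
            "focal_biomass_g": self.focal_biomass,
            "other_biomass_g": self.other_biomass,
        })

    def d_long(self) -> pd.DataFrame:
        """Full pairwise matrix in long format (receiver i, donor j)."""
        n = len(self.plants)
        recv, donor = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        return pd.DataFrame({
            "mesocosm_id": self.mesocosm_id,
            "receiver": [self.plants[i] for i in recv.ravel()],
            "donor": [self.plants[j] for j in donor.ravel()],
            "d": self.d.ravel(),
        })


@dataclass(frozen=True)
class DominanceSummary:
    """Group summary for the realised vs expected exotic-biomass comparison."""

    prop_exotic_planted: float
    herbivore_treatment: str
    n: int
    mean_realised_prop: float
    ci_low: float
    ci_high: float
    expected: float
    exceeds_expected: bool
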