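"""Assemble quantitative interaction webs and per-plant indices from survey records.

Converts long-format survey counts into survey-standardized herbivore biomass
per plant, per-mesocosm interaction matrices, the experiment-wide binary
meta-web (fundamental host ranges), informative-zero presence tables, and the
plant-level indices used downstream: normalized degree, percent leaf damage,
herbivore load and herbivore:plant biomass ratios.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import SpeciesLookupError
from .types import HerbivoreSpecies, InteractionMatrix, MetaWeb

#: ordinal leaf-damage category -> percent leaf area removed (range midpoints;
#: 0 = none, 1 = 1-5%, 2 = 6-25%, 3 = 26-50%, 4 = 51-75%, 5 = >75%)
DAMAGE_CATEGORY_PERCENT = {0: 0.0, 1: 3.0, 2: 15.5, 3: 38.0, 4: 63.0, 5: 88.0}


def _mass_lookup(herbivore_pool) -> dict[str, float]:
    """Accept a list of HerbivoreSpecies, a mapping, or a herbivore_species frame."""
    if isinstance(herbivore_pool, Mapping):
        return dict(herbivore_pool)
    if isinstance(herbivore_pool, pd.DataFrame):
        return dict(zip(herbivore_pool["species"], herbivore_pool["mean_dry_mass_g"]))
    return {h.species_id: h.mean_dry_mass for h in herbivore_pool}


def standardize_herbivore_biomass(surveys: pd.DataFrame,
                                  herbivore_pool,
                                  plant_outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-(plant, herbivore) standardized dry biomass in grams.

    For each plant individual and herbivore species, the total abundance
    summed over surveys is multiplied by the species' mean dry mass per
    individual and divided by the number of times that plant was surveyed
    (plants that died were surveyed fewer times).  Zero pairs are omitted;
    recover them with :func:`zero_fill_presence`.

    Returns columns ``mesocosm_id, plant_id, herbivore_species, biomass_g``.
    """
    mass = _mass_lookup(herbivore_pool)
    out_cols = ["mesocosm_id", "plant_id", "herbivore_species", "biomass_g"]
    if surveys.empty:
        return pd.DataFrame(columns=out_cols)

    unknown = set(surveys["herbivore_species"]) - set(mass)
    if unknown:
        raise SpeciesLookupError(
            f"no mean dry mass recorded for herbivore species: {sorted(unknown)}")

    n_obs = plant_outcomes.set_index("plant_id")["n_surveys_observed"]
    if (n_obs < 1).any():
        bad = n_obs.index[n_obs < 1].tolist()
        raise ValueError(f"n_surveys_observed < 1 for plants: {bad}")

    totals = (surveys.groupby(["mesocosm_id", "plant_id", "herbivore_species"],
                              as_index=False)["count"].sum())
    missing_plants = set(totals["plant_id"]) - set(n_obs.index)
    if missing_plants:
        raise SpeciesLookupError(
            f"survey records reference plants missing from outcomes: "
            f"{sorted(missing_plants)[:10]}")

    totals["biomass_g"] = (
        totals["count"]
        * totals["herbivore_species"].map(mass)
        / totals["plant_id"].map(n_obs).astype(float))
    totals = totals[totals["biomass_g"] > 0]
    return (totals[out_cols]
            .sort_values(["mesocosm_id", "plant_id", "herbivore_species"])
            .reset_index(drop=True))


def mesocosm_herbivore_biomass(surveys: pd.DataFrame,
                               herbivore_pool,
                               per_survey: bool = False,
                               n_surveys: int | None = None) -> pd.Series:
    """Total herbivore dry biomass per mesocosm in grams.

    Mean dry mass per individual times total abundance across all surveys,
    summed over herbivore species.  Deliberately *not* divided by the number
    of surveys (the per-plant standardization is); pass ``per_survey=True``
    with ``n_surveys`` for the normalized alternative.
    """
    mass = _mass_lookup(herbivore_pool)
    if surveys.empty:
        return pd.Series(dtype=float, name="herbivore_biomass_g")
    unknown = set(surveys["herbivore_species"]) - set(mass)
    if unknown:
        raise SpeciesLookupError(
            f"no mean dry mass recorded for herbivore species: {sorted(unknown)}")
    df = surveys.assign(biomass=surveys["count"] * surveys["herbivore_species"].map(mass))
    total = df.groupby("mesocosm_id")["biomass"].sum()
    if per_survey:
        if n_surveys is None:
            raise ValueError("per_survey=True requires n_surveys")
        total = total / n_surveys
    total.name = "herbivore_biomass_g"
    return total


def build_interaction_matrix(std_biomass: pd.DataFrame,
                             mesocosm_id: str,
                             plant_ids: Iterable[str],
                             herbivores: Iterable[str] | None = None) -> InteractionMatrix:
    """Assemble the plants x herbivores biomass matrix for one mesocosm.

    ``plant_ids`` must list every plant individual in the mesocosm design;
    plants with zero load are retained as zero rows.  If ``herbivores`` is
    None the column set is the species observed in this mesocosm.  Indices are
    sorted lexicographically, so the result is invariant to input row order.
    """
    plants = sorted(plant_ids)
    sub = std_biomass[std_biomass["mesocosm_id"] == mesocosm_id]
    stray = set(sub["plant_id"]) - set(plants)
    if stray:
        raise ValueError(
            f"observations reference plants absent from mesocosm {mesocosm_id}: "
            f"{sorted(stray)}")
    if herbivores is None:
        herbivores = sub["herbivore_species"].unique()
    herbivores = sorted(herbivores)

    alpha = np.zeros((len(plants), len(herbivores)))
    p_ix = {p: i for i, p in enumerate(plants)}
    h_ix = {h: j for j, h in enumerate(herbivores)}
    for row in sub.itertuples(index=False):
        alpha[p_ix[row.plant_id], h_ix[row.herbivore_species]] += row.biomass_g
    return InteractionMatrix(mesocosm_id, plants, herbivores, alpha)


def build_metaweb(std_biomass: pd.DataFrame,
                  plants: pd.DataFrame,
                  herbivore_pool) -> MetaWeb:
    """Experiment-wide binary web: 1 iff the species pair was realised anywhere.

    ``plants`` maps plant individuals to species and provenance (plants.csv
    schema); all pool species appear as rows/columns even if never realised.
    """
    if isinstance(herbivore_pool, pd.DataFrame):
        herb_ids = list(herbivore_pool["species"])
        herb_prov = dict(zip(herbivore_pool["species"], herbivore_pool["provenance"]))
    else:
        herb_ids = [h.species_id for h in herbivore_pool]
        herb_prov = {h.species_id: h.provenance.value
                     if isinstance(h, HerbivoreSpecies) else h.provenance
                     for h in herbivore_pool}
    plant_species = sorted(plants["species"].unique())
    plant_prov = dict(zip(plants["species"], plants["provenance"]))

    mat = pd.DataFrame(0, index=plant_species, columns=sorted(herb_ids), dtype=int)
    if not std_biomass.empty:
        sp = std_biomass.merge(plants[["plant_id", "species"]], on="plant_id", how="left")
        realised = sp[sp["biomass_g"] > 0][["species", "herbivore_species"]].drop_duplicates()
        for row in realised.itertuples(index=False):
            mat.loc[row.species, row.herbivore_species] = 1
    return MetaWeb(mat, plant_prov, herb_prov)


def zero_fill_presence(std_biomass: pd.DataFrame,
                       metaweb: MetaWeb,
                       plants: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence table restricted to each herbivore's fundamental host range.

    Emits exactly one row per (plant individual, herbivore) pair whose species
    pair is an edge of the meta-web: realised pairs with their biomass, and
    informative zeros for in-range pairs that were not realised.  Pairs
    outside the fundamental host range are discarded.
    """
    edges = (metaweb.matrix.stack().rename("in_range").reset_index()
             .rename(columns={"level_0": "species", "level_1": "herbivore_species"}))
    edges = edges[edges["in_range"] == 1].drop(columns="in_range")
    base = plants[["plant_id", "mesocosm_id", "species"]].merge(edges, on="species")
    out = base.merge(
        std_biomass[["plant_id", "herbivore_species", "biomass_g"]],
        on=["plant_id", "herbivore_species"], how="left")
    out["biomass_g"] = pd.to_numeric(out["biomass_g"], errors="coerce").fillna(0.0)
    out["presence"] = out["biomass_g"] > 0
    return (out[["mesocosm_id", "plant_id", "species", "herbivore_species",
                 "biomass_g", "presence"]]
            .sort_values(["mesocosm_id", "plant_id", "herbivore_species"])
            .reset_index(drop=True))


def normalized_degree(matrix: InteractionMatrix,
                      plant_id: str | None = None):
    """Proportion of the mesocosm's interacting herbivore species a plant feeds.

    The denominator is the number of herbivore species with at least one
    interaction in the mesocosm.  Returns a Series over plants, or a float for
    a single ``plant_id``.  Undefined (NaN, with a warning) when no herbivore
    species interacted in the mesocosm.
    """
    active = (matrix.alpha.sum(axis=0) > 0)
    n_active = int(active.sum())
    if n_active == 0:
        warnings.warn(
            f"mesocosm {matrix.mesocosm_id} has no interacting herbivore species; "
            "normalized degree is undefined", stacklevel=2)
        result = pd.Series(np.nan, index=matrix.plants, name="normalized_degree")
    else:
        per_plant = (matrix.alpha > 0).sum(axis=1) / n_active
        result = pd.Series(per_plant, index=matrix.plants, name="normalized_degree")
    if plant_id is not None:
        return float(result.loc[plant_id])
    return result


def damage_index(damage: pd.DataFrame, plant_id: str | None = None):
    """Mean percent leaf damage per plant over its surveys.

    Ordinal categories are mapped to midpoint percent values
    (:data:`DAMAGE_CATEGORY_PERCENT`) and averaged over the plant's surveys.
    """
    bad = ~damage["category"].isin(DAMAGE_CATEGORY_PERCENT)
    if bad.any():
        rows = damage.index[bad].tolist()[:10]
        raise ValueError(
            f"damage categories outside 0-5 at rows {rows}: "
            f"{sorted(damage.loc[bad, 'category'].unique())}")
    pct = damage["category"].map(DAMAGE_CATEGORY_PERCENT)
    result = pct.groupby(damage["plant_id"]).mean().rename("damage_pct")
    if plant_id is not None:
        return float(result.loc[plant_id])
    return result


def plant_biomass_ratio(std_biomass: pd.DataFrame,
                        plant_outcomes: pd.DataFrame) -> pd.Series:
    """Herbivore load : plant biomass ratio per plant (dimensionless).

    Total standardized herbivore biomass on the plant divided by its total
    (above+below ground) biomass.  Plants with zero biomass get NaN with a
    warning; plants with no herbivores get 0.
    """
    totals = plant_outcomes.set_index("plant_id")
    plant_total = (totals["aboveground_biomass_g"] + totals["belowground_biomass_g"])
    load = (std_biomass.groupby("plant_id")["biomass_g"].sum()
            .reindex(plant_total.index, fill_value=0.0))
    zero = plant_total <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} plants have zero total biomass; "
            "ratio undefined (NaN)", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = load / plant_total.where(~zero)
    ratio.name = "herbivore_plant_biomass_ratio"
    return ratio


def mesocosm_biomass_ratio(surveys: pd.DataFrame,
                           herbivore_pool,
                           plant_outcomes: pd.DataFrame) -> pd.DataFrame:
    """Mesocosm-level herbivore:plant biomass ratio, split by herbivore provenance.

    Numerators are un-normalized mesocosm herbivore biomass totals per
    provenance; the denominator is the summed biomass of the mesocosm's alive
    plants.
    """
    if isinstance(herbivore_pool, pd.DataFrame):
        prov = dict(zip(herbivore_pool["species"], herbivore_pool["provenance"]))
        mass = dict(zip(herbivore_pool["species"], herbivore_pool["mean_dry_mass_g"]))
    else:
        prov = {h.species_id: h.provenance.value for h in herbivore_pool}
        mass = {h.species_id: h.mean_dry_mass for h in herbivore_pool}

    alive = plant_outcomes[plant_outcomes["alive"]]
    plant_total = (alive.groupby("mesocosm_id")
                   .apply(lambda g: (g["aboveground_biomass_g"]
                                     + g["belowground_biomass_g"]).sum(),
                          include_groups=False))
    rows = []
    if not surveys.empty:
        df = surveys.assign(
            biomass=surveys["count"] * surveys["herbivore_species"].map(mass),
            herbivore_provenance=surveys["herbivore_species"].map(prov))
        herb_tot = df.groupby(["mesocosm_id", "herbivore_provenance"])["biomass"].sum()
    else:
        herb_tot = pd.Series(dtype=float)
    for meso in plant_total.index:
        denom = plant_total.loc[meso]
        for p in ("native", "exotic"):
            num = herb_tot.get((meso, p), 0.0)
            if denom <= 0:
                warnings.warn(f"mesocosm {meso} has zero plant biomass", stacklevel=2)
                ratio = np.nan
            else:
                ratio = num / denom
            rows.append({"mesocosm_id": meso, "herbivore_provenance": p,
                         "ratio": ratio})
    return pd.DataFrame(rows)


def plant_index_table(std_biomass: pd.DataFrame,
                      damage: pd.DataFrame,
                      plant_outcomes: pd.DataFrame,
                      matrices: Mapping[str, InteractionMatrix]) -> pd.DataFrame:
    """Combined per-plant index table: degree, damage, load and ratio."""
    nd_parts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in matrices.values():
            nd_parts.append(normalized_degree(m))
        ratio = plant_biomass_ratio(std_biomass, plant_outcomes)
    nd = pd.concat(nd_parts) if nd_parts else pd.Series(dtype=float, name="normalized_degree")
    dmg = damage_index(damage) if not damage.empty else pd.Series(dtype=float, name="damage_pct")
    load = std_biomass.groupby("plant_id")["biomass_g"].sum().rename("herbivore_load_g")

    out = plant_outcomes[["plant_id", "mesocosm_id", "species", "provenance", "alive"]].copy()
    out = (out
           .merge(nd.rename("normalized_degree"), left_on="plant_id",
                  right_index=True, how="left")
           .merge(dmg, left_on="plant_id", right_index=True, how="left")
           .merge(load, left_on="plant_id", right_index=True, how="left")
           .merge(ratio.rename("herbivore_plant_biomass_ratio"),
                  left_on="plant_id", right_index=True, how="left"))
    out["herbivore_load_g"] = out["herbivore_load_g"].fillna(0.0)
    return out.sort_values("plant_id").reset_index(drop=True)
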