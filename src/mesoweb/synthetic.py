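"""Synthetic mesocosm experiment generator.

Produces a factorial design (plant communities on crossed exotic/woody
gradients, herbivore and soil treatments), then simulates per-survey herbivore
counts, ordinal leaf-damage scores and end-of-experiment plant biomass with a
known, recoverable statistical structure:

* presence of a herbivore on a plant is Bernoulli per survey, with odds scaled
  by a configurable multiplier on exotic plants and thinned to a configurable
  retention in herbivore-removal mesocosms;
* counts given presence are shifted negative binomial with conditional mean
  scaled by a configurable multiplier on exotic plants (so biomass per
  realised interaction scales exactly by that multiplier);
* plant biomass is lognormal by provenance, with a configurable multiplicative
  herbivory penalty applied to exotic plants growing with herbivores.

All randomness flows from one master seed; each mesocosm (and each plant's
survival draw) uses an independent substream keyed by a stable hash of its
identifier, so subsetting a design never reshuffles other mesocosms.
"""
from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .errors import ConfigurationError
from .types import (
    CommunityDesign,
    ExperimentDesign,
    FunctionalGroup,
    Guild,
    HerbivoreSpecies,
    HerbivoreTreatment,
    MesocosmDesign,
    Origin,
    PlantSpecies,
    Provenance,
    SoilTreatment,
)

SURVEY_COLUMNS = ["mesocosm_id", "survey_index", "plant_id", "herbivore_species", "count"]
DAMAGE_COLUMNS = ["mesocosm_id", "survey_index", "plant_id", "category"]
PLANT_COLUMNS = ["plant_id", "mesocosm_id", "species", "provenance", "functional_group",
                 "alive", "aboveground_biomass_g", "belowground_biomass_g",
                 "n_surveys_observed"]

_STREAM_POOLS = 1
_STREAM_COMMUNITY = 2
_STREAM_SURVEY = 3
_STREAM_DAMAGE = 4
_STREAM_SURVIVAL = 5


def _rng(seed: int, key: str, stream: int) -> np.random.Generator:
    """Independent substream keyed by a stable hash of a string identifier."""
    return np.random.default_rng([seed, zlib.crc32(key.encode()), stream])


def _plant_survival(config: GeneratorConfig, plant_id: str) -> tuple[bool, int]:
    """(alive, n_surveys_observed) for one plant, from its private substream.

    Shared by the survey and harvest simulators so survey records and plant
    outcomes agree on when a plant died.
    """
    rng = _rng(config.seed, plant_id, _STREAM_SURVIVAL)
    dead = rng.random() < config.plant_death_prob
    if dead and config.n_surveys > 1:
        n_obs = int(rng.integers(1, config.n_surveys))
    else:
        n_obs = config.n_surveys
    return (not dead), n_obs


def _build_plant_pool(config: GeneratorConfig) -> list[PlantSpecies]:
    pool = []
    for i in range(config.n_native_plants):
        fg = FunctionalGroup.WOODY if i < config.n_woody_native else FunctionalGroup.HERBACEOUS
        pool.append(PlantSpecies(f"PN{i + 1:02d}", Provenance.NATIVE, fg))
    for i in range(config.n_exotic_plants):
        fg = FunctionalGroup.WOODY if i < config.n_woody_exotic else FunctionalGroup.HERBACEOUS
        pool.append(PlantSpecies(f"PX{i + 1:02d}", Provenance.EXOTIC, fg))
    return pool


def _build_herbivore_pool(config: GeneratorConfig,
                          plant_pool: list[PlantSpecies]) -> list[HerbivoreSpecies]:
    rng = _rng(config.seed, "herbivore_pool", _STREAM_POOLS)
    n_total = config.n_native_herbivores + config.n_exotic_herbivores
    plant_ids = [p.species_id for p in plant_pool]
    guilds = list(Guild)
    # origin assignment: first n_added species (in a fixed interleaved order) are
    # the deliberately added ones; the rest self-colonised
    origins = ([Origin.ADDED] * config.n_added_herbivores
               + [Origin.SELF_COLONISED] * (n_total - config.n_added_herbivores))
    rng.shuffle(origins)  # deterministic given seed

    lo, hi = config.host_range_fraction
    mu, sigma = config.herbivore_mass_lognormal
    pool = []
    for i in range(n_total):
        if i < config.n_native_herbivores:
            sid = f"HN{i + 1:02d}"
            prov = Provenance.NATIVE
        else:
            sid = f"HX{i - config.n_native_herbivores + 1:02d}"
            prov = Provenance.EXOTIC
        frac = rng.uniform(lo, hi)
        n_hosts = max(1, int(round(frac * len(plant_ids))))
        hosts = frozenset(rng.choice(plant_ids, size=n_hosts, replace=False).tolist())
        mass = float(rng.lognormal(mu, sigma))
        pool.append(HerbivoreSpecies(
            species_id=sid, provenance=prov, mean_dry_mass=mass,
            guild=guilds[i % len(guilds)], origin=origins[i],
            fundamental_hosts=hosts))
    return pool


def _build_community(config: GeneratorConfig, community_id: int,
                     n_exotic: int, n_woody: int,
                     plant_pool: list[PlantSpecies]) -> CommunityDesign:
    rng = _rng(config.seed, f"community:{community_id}", _STREAM_COMMUNITY)
    size = config.community_size
    n_native = size - n_exotic

    woody_ex = [p.species_id for p in plant_pool
                if p.provenance is Provenance.EXOTIC and p.functional_group is FunctionalGroup.WOODY]
    herb_ex = [p.species_id for p in plant_pool
               if p.provenance is Provenance.EXOTIC and p.functional_group is FunctionalGroup.HERBACEOUS]
    woody_na = [p.species_id for p in plant_pool
                if p.provenance is Provenance.NATIVE and p.functional_group is FunctionalGroup.WOODY]
    herb_na = [p.species_id for p in plant_pool
               if p.provenance is Provenance.NATIVE and p.functional_group is FunctionalGroup.HERBACEOUS]

    # split the woody quota between exotic and native members, proportionally,
    # clipped to what each side can accommodate
    w_ex = int(round(n_woody * n_exotic / size))
    w_ex = min(w_ex, n_exotic, len(woody_ex))
    w_na = n_woody - w_ex
    if w_na > min(n_native, len(woody_na)):
        # shift surplus back to the exotic side if possible
        spare = w_na - min(n_native, len(woody_na))
        w_na -= spare
        w_ex += spare
    if (w_ex > min(n_exotic, len(woody_ex)) or w_na > min(n_native, len(woody_na))
            or w_ex < 0 or w_na < 0):
        raise ConfigurationError(
            f"community {community_id}: cannot place {n_woody} woody species "
            f"with {n_exotic} exotics (pool has {len(woody_ex)} woody exotic, "
            f"{len(woody_na)} woody native species)")
    if n_exotic - w_ex > len(herb_ex) or n_native - w_na > len(herb_na):
        raise ConfigurationError(
            f"community {community_id}: herbaceous sub-pools too small for "
            f"{n_exotic} exotics / {n_woody} woody members")

    members = []
    for src, k in ((woody_ex, w_ex), (herb_ex, n_exotic - w_ex),
                   (woody_na, w_na), (herb_na, n_native - w_na)):
        if k:
            members.extend(rng.choice(src, size=k, replace=False).tolist())
    members = tuple(sorted(members))
    return CommunityDesign(
        community_id=community_id,
        members=members,
        prop_exotic_planted=n_exotic / size,
        prop_woody_planted=n_woody / size,
    )


def generate_design(config: GeneratorConfig) -> ExperimentDesign:
    """Generate species pools, communities and the crossed mesocosm layout.

    Deterministic given ``config.seed``.  With defaults this yields 20
    communities of 8 plant species drawn from a 39-species pool, crossed with
    2 herbivore x 2 soil treatments x 2 replicates = 160 mesocosms.
    """
    config.validate()
    plant_pool = _build_plant_pool(config)
    herbivore_pool = _build_herbivore_pool(config, plant_pool)

    exotic_counts = config.exotic_counts()
    woody_counts = config.woody_counts()
    communities = [
        _build_community(config, cid + 1, exotic_counts[cid], woody_counts[cid], plant_pool)
        for cid in range(config.n_communities)
    ]

    mesocosms = []
    idx = 0
    for comm in communities:
        for ht in config.herbivore_treatments:
            for st in config.soil_treatments:
                for rep in range(1, config.replicates + 1):
                    idx += 1
                    mesocosms.append(MesocosmDesign(
                        mesocosm_id=f"M{idx:03d}",
                        community_id=comm.community_id,
                        herbivore_treatment=HerbivoreTreatment(ht),
                        soil_treatment=SoilTreatment(st),
                        replicate=rep,
                    ))
    return ExperimentDesign(plant_pool, herbivore_pool, communities, mesocosms)


def simulate_surveys(design: ExperimentDesign, config: GeneratorConfig) -> pd.DataFrame:
    """Simulate per-survey herbivore counts on every plant individual.

    Returns a long-format frame with columns ``mesocosm_id, survey_index,
    plant_id, herbivore_species, count`` containing one row per realised
    (plant, herbivore, survey) presence; counts are >= 1.  Pairs outside a
    herbivore's fundamental host range are never produced.
    """
    herbs = sorted(design.herbivore_pool, key=lambda h: h.species_id)
    herb_ids = [h.species_id for h in herbs]
    herb_exotic = np.array([h.provenance is Provenance.EXOTIC for h in herbs])
    base_odds = (config.base_presence_prob / (1.0 - config.base_presence_prob)
                 if config.base_presence_prob < 1.0 else np.inf)

    frames = []
    for meso in design.mesocosms:
        rng = _rng(config.seed, meso.mesocosm_id, _STREAM_SURVEY)
        comm = design.community(meso.community_id)
        species = sorted(comm.members)
        n_p, n_k, n_s = len(species), len(herbs), config.n_surveys
        plant_exotic = np.array(
            [design.plant_species(s).provenance is Provenance.EXOTIC for s in species])
        eligible = np.array([[s in h.fundamental_hosts for h in herbs] for s in species])

        odds = np.full((n_p, n_k), base_odds)
        odds[plant_exotic, :] *= config.exotic_interaction_odds_multiplier
        odds[:, herb_exotic] *= np.exp(
            config.exotic_herbivore_prop_exotic_slope * comm.prop_exotic_planted)
        p = odds / (1.0 + odds)
        if meso.herbivore_treatment is HerbivoreTreatment.MINUS_H:
            p = p * config.minus_H_presence_retention
        p = np.where(eligible, p, 0.0)

        present = rng.random((n_s, n_p, n_k)) < p[None, :, :]

        # counts given presence: 1 + NB with conditional mean mu (exotic plants
        # get mu scaled by the biomass multiplier, exactly)
        mu = np.where(plant_exotic,
                      config.mean_count_given_presence * config.exotic_biomass_multiplier,
                      config.mean_count_given_presence)
        m = np.maximum(mu - 1.0, 0.0)
        k_disp = config.count_dispersion
        p_nb = k_disp / (k_disp + m)  # p=1 when m=0 -> NB draw is always 0
        counts = 1 + rng.negative_binomial(
            k_disp, np.broadcast_to(p_nb[None, :, None], (n_s, n_p, n_k)))

        # truncate after plant death (fixed number of RNG draws regardless)
        n_obs = np.array([
            _plant_survival(config, design.plant_id(meso.mesocosm_id, s))[1]
            for s in species])
        survey_alive = np.arange(1, n_s + 1)[:, None] <= n_obs[None, :]
        present &= survey_alive[:, :, None]

        s_idx, p_idx, k_idx = np.nonzero(present)
        if len(s_idx) == 0:
            continue
        frames.append(pd.DataFrame({
            "mesocosm_id": meso.mesocosm_id,
            "survey_index": s_idx + 1,
            "plant_id": [design.plant_id(meso.mesocosm_id, species[i]) for i in p_idx],
            "herbivore_species": [herb_ids[j] for j in k_idx],
            "count": counts[s_idx, p_idx, k_idx],
        }))

    if not frames:
        return pd.DataFrame(columns=SURVEY_COLUMNS).astype(
            {"survey_index": int, "count": int})
    out = pd.concat(frames, ignore_index=True)
    return out[SURVEY_COLUMNS]


def simulate_damage_and_biomass(
        design: ExperimentDesign,
        surveys: pd.DataFrame,
        config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ordinal damage scores and harvest biomass for every plant.

    Returns ``(damage, plants)``: damage has columns ``mesocosm_id,
    survey_index, plant_id, category`` (categories 0..5, only surveys the
    plant was alive for); plants follows the plants.csv schema.  Exotic plants
    growing with herbivores have expected biomass reduced by the configured
    herbivory penalty.  The ``surveys`` argument is accepted for pipeline
    symmetry; damage is drawn from the configured category distributions
    rather than from realised loads.
    """
    del surveys  # damage is not conditioned on realised counts
    damage_rows = []
    plant_rows = []
    for meso in design.mesocosms:
        rng = _rng(config.seed, meso.mesocosm_id, _STREAM_DAMAGE)
        comm = design.community(meso.community_id)
        species = sorted(comm.members)
        minus_h = meso.herbivore_treatment is HerbivoreTreatment.MINUS_H
        for sp in species:
            attrs = design.plant_species(sp)
            pid = design.plant_id(meso.mesocosm_id, sp)
            alive, n_obs = _plant_survival(config, pid)

            probs = np.asarray(
                config.damage_category_probabilities[attrs.provenance.value], dtype=float)
            cats = rng.choice(6, size=config.n_surveys, p=probs)
            if minus_h:
                # removal thins non-zero damage down to the damage retention
                keep = rng.random(config.n_surveys) < config.minus_H_damage_retention
                cats = np.where(keep, cats, 0)
            for s in range(n_obs):
                damage_rows.append((meso.mesocosm_id, s + 1, pid, int(cats[s])))

            mu, sigma = config.plant_growth[attrs.provenance.value]
            total = float(rng.lognormal(mu, sigma))
            if attrs.provenance is Provenance.EXOTIC and not minus_h:
                total *= (1.0 - config.herbivory_biomass_penalty_exotic)
            if meso.soil_treatment is SoilTreatment.HOME:
                total *= config.soil_home_biomass_multiplier
            if not alive:
                # died partway: harvested remnant scales with time alive
                total *= 0.5 * n_obs / config.n_surveys
            above = total * rng.beta(*config.aboveground_beta)
            plant_rows.append({
                "plant_id": pid,
                "mesocosm_id": meso.mesocosm_id,
                "species": sp,
                "provenance": attrs.provenance.value,
                "functional_group": attrs.functional_group.value,
                "alive": alive,
                "aboveground_biomass_g": above,
                "belowground_biomass_g": total - above,
                "n_surveys_observed": n_obs,
            })

    damage = pd.DataFrame(damage_rows, columns=DAMAGE_COLUMNS)
    plants = pd.DataFrame(plant_rows, columns=PLANT_COLUMNS)
    return damage, plants


def write_dataset(design: ExperimentDesign, surveys: pd.DataFrame,
                  damage: pd.DataFrame, plants: pd.DataFrame,
                  config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the five CSV tables plus a ground-truth sidecar JSON.

    The sidecar echoes the generator parameters and fundamental host ranges so
    parameter-recovery tests can compare pipeline estimates against truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    tables = {
        "mesocosms.csv": design.mesocosm_table(),
        "plant_species.csv": design.plant_species_table(),
        "herbivore_species.csv": design.herbivore_species_table(),
        "plants.csv": plants,
        "surveys.csv": surveys[SURVEY_COLUMNS],
        "damage.csv": damage[DAMAGE_COLUMNS],
    }
    for name, df in tables.items():
        path = outdir / name
        df.to_csv(path, index=False)
        paths[name] = path

    truth = {
        "config": config.to_dict(),
        "fundamental_hosts": {h.species_id: sorted(h.fundamental_hosts)
                              for h in design.herbivore_pool},
    }
    truth_path = outdir / "ground_truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    paths["ground_truth.json"] = truth_path
    return paths


def generate_dataset(config: GeneratorConfig) -> dict[str, object]:
    """Convenience wrapper: design + all simulated tables in one call."""
    design = generate_design(config)
    surveys = simulate_surveys(design, config)
    damage, plants = simulate_damage_and_biomass(design, surveys, config)
    return {"design": design, "surveys": surveys, "damage": damage, "plants": plants}
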