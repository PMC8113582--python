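"""Network assembly: standardization arithmetic, matrices, meta-web, indices."""
import numpy as np
import pandas as pd
import pytest

from mesoweb import (
    DAMAGE_CATEGORY_PERCENT,
    SpeciesLookupError,
    build_interaction_matrix,
    build_metaweb,
    damage_index,
    mesocosm_herbivore_biomass,
    normalized_degree,
    plant_biomass_ratio,
    standardize_herbivore_biomass,
    zero_fill_presence,
)
from mesoweb.types import InteractionMatrix, MetaWeb


def surveys_frame(rows):
    return pd.DataFrame(
        rows, columns=["mesocosm_id", "survey_index", "plant_id",
                       "herbivore_species", "count"])


def outcomes_frame(rows):
    cols = ["plant_id", "mesocosm_id", "species", "provenance",
            "functional_group", "alive", "aboveground_biomass_g",
            "belowground_biomass_g", "n_surveys_observed"]
    return pd.DataFrame(rows, columns=cols)


def simple_outcome(plant_id, n_obs=8, species="sp1", provenance="native",
                   above=5.0, below=5.0, alive=True, mesocosm="M1"):
    return (plant_id, mesocosm, species, provenance, "herbaceous", alive,
            above, below, n_obs)


class TestStandardizeBiomass:
    def test_worked_example(self):
        # counts (2, 3, 5) over 8 surveys at 0.02 g/individual -> 0.025 g
        surveys = surveys_frame([("M1", 1, "p1", "h1", 2),
                                 ("M1", 3, "p1", "h1", 3),
                                 ("M1", 7, "p1", "h1", 5)])
        outcomes = outcomes_frame([simple_outcome("p1", 8)])
        out = standardize_herbivore_biomass(surveys, {"h1": 0.02}, outcomes)
        assert len(out) == 1
        assert out.loc[0, "biomass_g"] == pytest.approx(10 * 0.02 / 8)

    def test_reduced_denominator_for_dead_plant(self):
        # plant surveyed 4 times, counts (4, 4), mass 0.1 -> 8 * 0.1 / 4 = 0.2
        surveys = surveys_frame([("M1", 1, "p1", "h1", 4),
                                 ("M1", 2, "p1", "h1", 4)])
        outcomes = outcomes_frame([simple_outcome("p1", 4, alive=False)])
        out = standardize_herbivore_biomass(surveys, {"h1": 0.1}, outcomes)
        assert out.loc[0, "biomass_g"] == pytest.approx(0.2)

    def test_all_zero_counts_give_empty_output(self):
        surveys = surveys_frame([("M1", 1, "p1", "h1", 0)])
        outcomes = outcomes_frame([simple_outcome("p1", 8)])
        out = standardize_herbivore_biomass(surveys, {"h1": 0.1}, outcomes)
        assert out.empty

    def test_missing_mass_names_species(self):
        surveys = surveys_frame([("M1", 1, "p1", "weevil_x", 1)])
        outcomes = outcomes_frame([simple_outcome("p1", 8)])
        with pytest.raises(SpeciesLookupError, match="weevil_x"):
            standardize_herbivore_biomass(surveys, {"other": 0.1}, outcomes)

    def test_order_invariance(self):
        rows = [("M1", s, p, h, c)
                for s, p, h, c in [(1, "p1", "h1", 2), (2, "p2", "h2", 3),
                                   (3, "p1", "h2", 1), (2, "p1", "h1", 4)]]
        outcomes = outcomes_frame([simple_outcome("p1", 8),
                                   simple_outcome("p2", 8)])
        mass = {"h1": 0.1, "h2": 0.2}
        a = standardize_herbivore_biomass(surveys_frame(rows), mass, outcomes)
        b = standardize_herbivore_biomass(
            surveys_frame(rows[::-1]), mass, outcomes)
        pd.testing.assert_frame_equal(a, b)


class TestMesocosmBiomass:
    def test_single_species(self):
        # abundance 10 over all surveys at 0.02 g -> 0.2 g (not survey-normalized)
        surveys = surveys_frame([("M1", 1, "p1", "h1", 6),
                                 ("M1", 2, "p1", "h1", 4)])
        total = mesocosm_herbivore_biomass(surveys, {"h1": 0.02})
        assert total.loc["M1"] == pytest.approx(0.2)

    def test_empty_mesocosm(self):
        total = mesocosm_herbivore_biomass(surveys_frame([]), {"h1": 0.02})
        assert total.empty

    def test_additivity_over_species(self):
        surveys = surveys_frame([("M1", 1, "p1", "h1", 10),
                                 ("M1", 1, "p1", "h2", 5)])
        total = mesocosm_herbivore_biomass(surveys, {"h1": 0.02, "h2": 0.1})
        assert total.loc["M1"] == pytest.approx(10 * 0.02 + 5 * 0.1)

    def test_per_survey_flag(self):
        surveys = surveys_frame([("M1", 1, "p1", "h1", 10)])
        total = mesocosm_herbivore_biomass(surveys, {"h1": 0.02},
                                           per_survey=True, n_surveys=8)
        assert total.loc["M1"] == pytest.approx(0.2 / 8)


class TestInteractionMatrix:
    def std(self, rows):
        return pd.DataFrame(rows, columns=["mesocosm_id", "plant_id",
                                           "herbivore_species", "biomass_g"])

    def test_shared_herbivore(self):
        std = self.std([("M1", "p1", "h1", 0.025), ("M1", "p2", "h1", 0.025)])
        m = build_interaction_matrix(std, "M1", ["p1", "p2"])
        assert m.alpha.shape == (2, 1)
        np.testing.assert_allclose(m.alpha, [[0.025], [0.025]])

    def test_empty_gives_zero_matrix_of_design_dimensions(self):
        m = build_interaction_matrix(self.std([]), "M1", ["p1", "p2"],
                                     herbivores=["h1", "h2", "h3"])
        assert m.alpha.shape == (2, 3)
        assert (m.alpha == 0).all()

    def test_row_order_invariance(self):
        rows = [("M1", "p2", "h2", 0.3), ("M1", "p1", "h1", 0.1),
                ("M1", "p1", "h2", 0.2)]
        a = build_interaction_matrix(self.std(rows), "M1", ["p1", "p2"])
        b = build_interaction_matrix(self.std(rows[::-1]), "M1", ["p2", "p1"])
        np.testing.assert_array_equal(a.alpha, b.alpha)
        assert a.plants == b.plants and a.herbivores == b.herbivores

    def test_unknown_plant_raises(self):
        std = self.std([("M1", "ghost", "h1", 0.1)])
        with pytest.raises(ValueError, match="ghost"):
            build_interaction_matrix(std, "M1", ["p1"])

    def test_matches_naive_accumulation(self):
        # oracle: literal per-record accumulation loop on small instances
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_p = rng.integers(1, 6)
            n_h = rng.integers(1, 6)
            plants = [f"p{i}" for i in range(n_p)]
            herbs = [f"h{j}" for j in range(n_h)]
            n_rec = int(rng.integers(0, 15))
            rows = [("M1", plants[rng.integers(n_p)], herbs[rng.integers(n_h)],
                     float(rng.uniform(0.01, 1))) for _ in range(n_rec)]
            expected = np.zeros((n_p, n_h))
            for _, p, h, b in rows:
                expected[plants.index(p), herbs.index(h)] += b
            m = build_interaction_matrix(self.std(rows), "M1", plants, herbs)
            np.testing.assert_allclose(m.alpha, expected, atol=1e-12)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            InteractionMatrix("M1", ["p1"], ["h1"], np.array([[-0.1]]))


class TestMetaWeb:
    def plants(self):
        return pd.DataFrame({
            "plant_id": ["M1:a", "M1:b", "M2:a"],
            "mesocosm_id": ["M1", "M1", "M2"],
            "species": ["a", "b", "a"],
            "provenance": ["native", "exotic", "native"],
        })

    def pool(self):
        return pd.DataFrame({"species": ["h1", "h2"],
                             "provenance": ["native", "exotic"],
                             "mean_dry_mass_g": [0.1, 0.2]})

    def test_union_semantics(self):
        # realised in exactly one mesocosm -> edge 1; never realised -> 0
        std = pd.DataFrame({"mesocosm_id": ["M2"], "plant_id": ["M2:a"],
                            "herbivore_species": ["h1"], "biomass_g": [0.5]})
        web = build_metaweb(std, self.plants(), self.pool())
        assert web.matrix.loc["a", "h1"] == 1
        assert web.matrix.loc["a", "h2"] == 0
        assert web.matrix.loc["b", "h1"] == 0

    def test_monotone_under_added_observations(self):
        std1 = pd.DataFrame({"mesocosm_id": ["M1"], "plant_id": ["M1:a"],
                             "herbivore_species": ["h1"], "biomass_g": [0.5]})
        std2 = pd.concat([std1, pd.DataFrame(
            {"mesocosm_id": ["M1"], "plant_id": ["M1:b"],
             "herbivore_species": ["h2"], "biomass_g": [0.1]})],
            ignore_index=True)
        w1 = build_metaweb(std1, self.plants(), self.pool())
        w2 = build_metaweb(std2, self.plants(), self.pool())
        assert ((w2.matrix - w1.matrix) >= 0).all().all()

    def test_closure_against_generator_truth(self, small_dataset):
        design = small_dataset["design"]
        std = standardize_herbivore_biomass(
            small_dataset["surveys"], design.herbivore_pool,
            small_dataset["plants"])
        web = build_metaweb(std, small_dataset["plants"], design.herbivore_pool)
        for h in design.herbivore_pool:
            realised = set(web.hosts_of(h.species_id)) if h.species_id in web.matrix else set()
            assert realised <= h.fundamental_hosts


class TestZeroFill:
    def metaweb(self, mat, plant_species, herbs):
        return MetaWeb(pd.DataFrame(mat, index=plant_species, columns=herbs))

    def plants8(self):
        species = [f"s{i}" for i in range(8)]
        return pd.DataFrame({
            "plant_id": [f"M1:{s}" for s in species],
            "mesocosm_id": "M1",
            "species": species,
            "provenance": "native",
        })

    def test_row_count_matches_host_range(self):
        species = [f"s{i}" for i in range(8)]
        mat = np.zeros((8, 1), dtype=int)
        mat[[0, 3, 5], 0] = 1  # 3 fundamental hosts of the only herbivore
        web = self.metaweb(mat, species, ["h1"])
        out = zero_fill_presence(pd.DataFrame(
            columns=["mesocosm_id", "plant_id", "herbivore_species", "biomass_g"]),
            web, self.plants8())
        assert len(out) == 3
        assert not out["presence"].any()

    def test_all_ones_metaweb(self):
        species = [f"s{i}" for i in range(8)]
        web = self.metaweb(np.ones((8, 2), dtype=int), species, ["h1", "h2"])
        out = zero_fill_presence(pd.DataFrame(
            columns=["mesocosm_id", "plant_id", "herbivore_species", "biomass_g"]),
            web, self.plants8())
        assert len(out) == 8 * 2

    def test_all_zero_metaweb(self):
        species = [f"s{i}" for i in range(8)]
        web = self.metaweb(np.zeros((8, 2), dtype=int), species, ["h1", "h2"])
        out = zero_fill_presence(pd.DataFrame(
            columns=["mesocosm_id", "plant_id", "herbivore_species", "biomass_g"]),
            web, self.plants8())
        assert out.empty

    def test_presence_marks_realised_pairs(self):
        species = [f"s{i}" for i in range(8)]
        mat = np.zeros((8, 1), dtype=int)
        mat[[0, 3, 5], 0] = 1
        web = self.metaweb(mat, species, ["h1"])
        std = pd.DataFrame({"mesocosm_id": ["M1"], "plant_id": ["M1:s3"],
                            "herbivore_species": ["h1"], "biomass_g": [0.4]})
        out = zero_fill_presence(std, web, self.plants8())
        assert len(out) == 3
        assert out.set_index("plant_id")["presence"].to_dict() == {
            "M1:s0": False, "M1:s3": True, "M1:s5": False}


class TestNormalizedDegree:
    def matrix(self, alpha):
        alpha = np.asarray(alpha, float)
        plants = [f"p{i}" for i in range(alpha.shape[0])]
        herbs = [f"h{j}" for j in range(alpha.shape[1])]
        return InteractionMatrix("M1", plants, herbs, alpha)

    def test_half(self):
        alpha = np.zeros((2, 8))
        alpha[0, :4] = 1.0  # focal plant fed on by 4 herbivores
        alpha[1, :] = 1.0   # all 8 herbivore species active in the mesocosm
        assert normalized_degree(self.matrix(alpha), "p0") == 0.5

    def test_zero_load_plant(self):
        alpha = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert normalized_degree(self.matrix(alpha), "p0") == 0.0

    def test_full_degree(self):
        alpha = np.ones((3, 5))
        assert normalized_degree(self.matrix(alpha), "p1") == 1.0

    def test_no_herbivores_warns_and_is_nan(self):
        alpha = np.zeros((2, 3))
        with pytest.warns(UserWarning, match="undefined"):
            out = normalized_degree(self.matrix(alpha))
        assert out.isna().all()


class TestDamageIndex:
    def damage(self, cats, plant_id="p1"):
        return pd.DataFrame({"mesocosm_id": "M1",
                             "survey_index": range(1, len(cats) + 1),
                             "plant_id": plant_id, "category": cats})

    def test_category_three_is_38_percent(self):
        assert damage_index(self.damage([3]), "p1") == 38.0

    def test_category_mapping_table(self):
        assert DAMAGE_CATEGORY_PERCENT == {0: 0.0, 1: 3.0, 2: 15.5, 3: 38.0,
                                           4: 63.0, 5: 88.0}

    def test_mean_over_surveys(self):
        assert damage_index(self.damage([0, 1, 3]), "p1") == pytest.approx(
            (0 + 3 + 38) / 3)

    def test_all_zero(self):
        assert damage_index(self.damage([0, 0, 0]), "p1") == 0.0

    def test_invalid_category_raises(self):
        with pytest.raises(ValueError, match="outside 0-5"):
            damage_index(self.damage([2, 7]), "p1")


class TestBiomassRatio:
    def test_basic_ratio(self):
        std = pd.DataFrame({"mesocosm_id": ["M1"], "plant_id": ["p1"],
                            "herbivore_species": ["h1"], "biomass_g": [0.5]})
        outcomes = outcomes_frame([simple_outcome("p1", 8, above=6.0, below=4.0)])
        ratio = plant_biomass_ratio(std, outcomes)
        assert ratio.loc["p1"] == pytest.approx(0.05)

    def test_zero_herbivores(self):
        std = pd.DataFrame(columns=["mesocosm_id", "plant_id",
                                    "herbivore_species", "biomass_g"])
        outcomes = outcomes_frame([simple_outcome("p1", 8)])
        assert plant_biomass_ratio(std, outcomes).loc["p1"] == 0.0

    def test_scale_invariance(self):
        std = pd.DataFrame({"mesocosm_id": ["M1"], "plant_id": ["p1"],
                            "herbivore_species": ["h1"], "biomass_g": [1.0]})
        out1 = outcomes_frame([simple_outcome("p1", 8, above=6.0, below=4.0)])
        std2 = std.assign(biomass_g=std["biomass_g"] * 2)
        out2 = outcomes_frame([simple_outcome("p1", 8, above=12.0, below=8.0)])
        assert (plant_biomass_ratio(std, out1).loc["p1"]
                == pytest.approx(plant_biomass_ratio(std2, out2).loc["p1"]))

    def test_zero_plant_biomass_warns(self):
        std = pd.DataFrame({"mesocosm_id": ["M1"], "plant_id": ["p1"],
                            "herbivore_species": ["h1"], "biomass_g": [1.0]})
        outcomes = outcomes_frame([simple_outcome("p1", 8, above=0.0, below=0.0)])
        with pytest.warns(UserWarning, match="zero total biomass"):
            ratio = plant_biomass_ratio(std, outcomes)
        assert np.isnan(ratio.loc["p1"])


class TestConservation:
    def test_standardized_totals_conserved_without_deaths(self):
        # With all plants sharing n_surveys_observed, summing standardized
        # per-plant biomass over plants recovers each herbivore's
        # survey-normalized total.
        from conftest import small_generator_config
        from mesoweb import generate_dataset

        cfg = small_generator_config(seed=11, plant_death_prob=0.0)
        data = generate_dataset(cfg)
        design = data["design"]
        std = standardize_herbivore_biomass(
            data["surveys"], design.herbivore_pool, data["plants"])
        mass = {h.species_id: h.mean_dry_mass for h in design.herbivore_pool}
        per_herb_std = std.groupby("herbivore_species")["biomass_g"].sum()
        counts = data["surveys"].groupby("herbivore_species")["count"].sum()
        for herb, total in per_herb_std.items():
            expected = counts[herb] * mass[herb] / cfg.n_surveys
            assert total == pytest.approx(expected, rel=1e-9)
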