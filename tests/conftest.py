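import pandas as pd
import pytest

from mesoweb import GeneratorConfig, generate_dataset, generate_design

EMPTY_SURVEYS = pd.DataFrame(
    columns=["mesocosm_id", "survey_index", "plant_id", "herbivore_species", "count"])


def small_generator_config(seed=7, **overrides):
    """Reduced-size generator: 5 communities x 2 H x 1 soil x 1 rep, 4 surveys."""
    kw = dict(
        seed=seed,
        n_communities=5,
        replicates=1,
        soil_treatments=("home",),
        n_surveys=4,
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_design(default_config):
    return generate_design(default_config)


@pytest.fixture(scope="session")
def small_config():
    return small_generator_config()


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)
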