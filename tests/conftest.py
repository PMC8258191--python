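import numpy as np
import pandas as pd
import pytest

import mesozoo as mz


@pytest.fixture(scope="session")
def reference_tables():
    return mz.load_reference_tables()


@pytest.fixture(scope="session")
def taxa_table(reference_tables):
    return reference_tables[0]


@pytest.fixture(scope="session")
def registry():
    return mz.default_registry()


@pytest.fixture(scope="session")
def default_survey():
    """One default-scenario survey with truth, shared across tests."""
    config = mz.default_scenario()
    bundle, truth = mz.simulate_survey(config, seed=7)
    return config, bundle, truth


@pytest.fixture(scope="session")
def processed_default(default_survey):
    _, bundle, _ = default_survey
    biomass, controls = mz.process_survey(bundle.weighings)
    return biomass, controls


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def community_matrix(processed_default):
    """Samples × taxa areal-biomass matrix from the shared survey."""
    biomass, _ = processed_default
    reliable = biomass[biomass["reliable"]]
    return reliable.pivot_table(
        index="sample_id",
        columns="taxon_name",
        values="areal_biomass",
        aggfunc="sum",
        fill_value=0.0,
    )
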