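import numpy as np
import pytest

import ricelai
from ricelai.simulate import noiseless_config


@pytest.fixture(scope="session")
def default_obs():
    """The default synthetic campaign: 30 plots x 9 stages, seed 0."""
    return ricelai.generate_dataset(ricelai.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_obs():
    return ricelai.generate_dataset(noiseless_config())


@pytest.fixture(scope="session")
def feature_table(default_obs):
    return ricelai.build_feature_table(default_obs)


@pytest.fixture(scope="session")
def ranking(feature_table):
    return ricelai.rank_importance(feature_table, seed=0)


@pytest.fixture(scope="session")
def sequence_data(feature_table, ranking):
    selected = ricelai.select_top_k(ranking, 6)
    return ricelai.build_sequences(feature_table, selected)


@pytest.fixture(scope="session")
def tarp_anchors():
    """Three calibration tarps per band at known reflectances."""
    return [
        ricelai.TarpAnchor("b842", dn, refl)
        for dn, refl in [(1000, 0.10), (3000, 0.30), (5000, 0.50)]
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
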