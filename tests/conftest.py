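import warnings

import numpy as np
import pandas as pd
import pytest

from mosscrust.community import OtuTable
from mosscrust.config import SimulationConfig
from mosscrust.simulate import (
    generate_microbiome,
    generate_physiology,
    generate_survey,
)

# reduced problem sizes for unit tests; statistical structure unchanged
SMALL = dict(n_features=400, n_genera=120, library_size_mean=20000)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=42, **SMALL)


@pytest.fixture(scope="session")
def microbiome_sim(small_config):
    return generate_microbiome(small_config)


@pytest.fixture(scope="session")
def survey_sim(small_config):
    return generate_survey(small_config)


@pytest.fixture(scope="session")
def physio_sim(small_config):
    return generate_physiology(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def tiny_table() -> OtuTable:
    counts = pd.DataFrame(
        [[5, 3, 0, 1], [0, 2, 4, 1], [7, 0, 1, 0]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2", "f3", "f4"],
    )
    return OtuTable(counts)
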