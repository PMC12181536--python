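import warnings

import numpy as np
import pytest

from senetrace import synthetic as syn
from senetrace.model import SenescenceTrajectoryModel


@pytest.fixture(scope="session")
def small_scenario():
    return syn.default_scenario(cells_per_time_point=150, rng_seed=2)


@pytest.fixture(scope="session")
def small_tables(small_scenario):
    return syn.sample_cells(small_scenario)


@pytest.fixture(scope="session")
def noisefree_scene():
    """A rendered noise-free phantom with known inter-round offsets."""
    scen = syn.default_scenario(cells_per_time_point=50, rng_seed=3,
                                sigma_measurement=0.0)
    return syn.render_scene(scen, day=11, field_size=(520, 520), n_cells=10,
                            offsets=[(0, 0), (4, -2), (1, 1), (0, 0), (2, 3), (0, -1)])


@pytest.fixture(scope="session")
def fitted(small_tables):
    """One full model fit (embedding + clustering + lineages) shared by the
    slower integration tests."""
    feat, truth = small_tables
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = SenescenceTrajectoryModel(feat).fit(
            seed=2, subsample_n=150, k_range=range(2, 13), n_init=5)
    return res, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
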