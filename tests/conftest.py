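import numpy as np
import pytest

import pmdisparity as pm


@pytest.fixture(scope="session")
def small_sim():
    """Small but structurally complete simulation: 2 states x 2 districts."""
    return pm.SimulationConfig(
        n_states=2, districts_per_state=2, clusters_per_district=12,
        grid_shape=(60, 60), seed=123,
    )


@pytest.fixture(scope="session")
def small_world(small_sim):
    conc = pm.generate_concentration_field(small_sim)
    settlement = pm.generate_settlement_raster(small_sim, conc)
    clusters = pm.generate_clusters(small_sim, conc, settlement)
    return small_sim, conc, settlement, clusters


@pytest.fixture(scope="session")
def default_world():
    """Default-size world (10 states x 5 districts x 20 clusters = 1000)."""
    cfg = pm.SimulationConfig(seed=20240901)
    conc = pm.generate_concentration_field(cfg)
    settlement = pm.generate_settlement_raster(cfg, conc)
    clusters = pm.generate_clusters(cfg, conc, settlement)
    return cfg, conc, settlement, clusters


@pytest.fixture(scope="session")
def small_exposures(small_world):
    _, conc, _, clusters = small_world
    return pm.assign_cluster_exposure(clusters, conc, pm.BufferPolicy())


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
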