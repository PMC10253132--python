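import numpy as np
import pytest

import binmapqtl as bq


@pytest.fixture(scope="session")
def thin_map():
    """19-group template map thinned to ~400 sites for fast experiments."""
    return bq.default_map(n_sites=400)


@pytest.fixture(scope="session")
def full_map():
    """Full template geometry: 19 groups, 4148 sites, 1618.3 cM."""
    return bq.default_map()


@pytest.fixture(scope="session")
def dense_single_group():
    """One 100 cM chromosome with 10 sites/cM — dense enough that window
    genotyping resolves essentially every crossover."""
    return bq.SimMap([bq.SimGroup("A01", 100.0, np.linspace(0, 100, 1000),
                                  np.arange(1, 1001) * 10_000, 10_100_000)])


@pytest.fixture(scope="session")
def f2_population(thin_map):
    return bq.simulate_f2(thin_map, 196, seed=11)
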