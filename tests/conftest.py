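import numpy as np
import pandas as pd
import pytest

from demeflow.config import SimConfig, scaled_config
from demeflow.engine import ParameterSet
from demeflow.fixtures import default_fixture
from demeflow.geography import DemeNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_fixture():
    """Four-island archipelago used for fast end-to-end runs."""
    return default_fixture(n_islands=4, demes_per_island=4, seed=0)


@pytest.fixture(scope="session")
def tiny_config():
    return scaled_config(pop_scale=0.17, steps=100)


@pytest.fixture
def fitted_params():
    """The study's most probable parameter regime."""
    return ParameterSet(
        m_a=0.51, m_p=0.31, f_a=3.9, f_p=5.7, marriage_weight=0.23,
        start_distribution="D000",
    )


def make_deme_table(coords, sources=(), regions=None, islands=None):
    """Deme table from a list of (lon, lat) pairs."""
    rows = []
    for k, (lon, lat) in enumerate(coords):
        rows.append(
            {
                "id": f"d{k}",
                "lon": lon,
                "lat": lat,
                "island": islands[k] if islands else f"isl{k}",
                "region": regions[k] if regions else f"r{k}",
                "is_source": int(k in sources),
            }
        )
    return pd.DataFrame(rows, columns=["id", "lon", "lat", "island", "region", "is_source"])


@pytest.fixture
def isolated_pair_network():
    """Two demes too far apart to connect: two closed populations."""
    table = make_deme_table([(100.0, 0.0), (150.0, 60.0)])
    with pytest.warns(UserWarning, match="isolated"):
        return DemeNetwork(table)
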