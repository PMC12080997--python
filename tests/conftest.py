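import numpy as np
import pytest

from molconn.atlas import build_toy_atlas, load_region_table


@pytest.fixture(scope="session")
def region_table():
    return load_region_table()


@pytest.fixture(scope="session")
def toy_atlas(region_table):
    return build_toy_atlas(region_table=region_table)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
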