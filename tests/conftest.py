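import numpy as np
import pytest

import landcarbon as lc


@pytest.fixture(scope="session")
def small_scenario():
    return lc.default_scenario(grid_rows=80, grid_cols=80, seed=11,
                               epoch_years=(2000, 2010, 2020))


@pytest.fixture(scope="session")
def small_maps(small_scenario):
    return lc.generate_lulc_series(small_scenario)


@pytest.fixture
def toy_map_pair():
    """2x2 toy: t1=[F,F;C,C], t2=[F,C;C,C] with F=1, C=3."""
    codes = (1, 3)
    t1 = lc.LulcMap(np.array([[1, 1], [3, 3]], dtype=np.uint8), codes)
    t2 = lc.LulcMap(np.array([[1, 3], [3, 3]], dtype=np.uint8), codes)
    return t1, t2


def make_map(data, codes=(1, 2, 3), **kw):
    return lc.LulcMap(np.asarray(data, dtype=np.uint8), codes, **kw)


@pytest.fixture
def map_factory():
    return make_map
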