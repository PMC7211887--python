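import numpy as np
import pytest

from strainmosaic import make_reference, mutate_strain


@pytest.fixture(scope="session")
def small_reference():
    return make_reference("sp_test", 5000, gc_fraction=0.5, seed=101)


@pytest.fixture(scope="session")
def small_strain(small_reference):
    return mutate_strain(small_reference, 0.005, seed=202, lineage_id="L0")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
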