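import numpy as np
import pytest

from zapped import PoolParams, default_schedule, forward_zspectrum, tissue_presets

SEED = 20150313


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def gm_params():
    """Healthy gray-matter group means: F_r=0.17, T2_f=785 us, T2_r=17.7 us."""
    return PoolParams.from_t2(0.17, 785.0, 17.7)


@pytest.fixture(scope="session")
def wm_params():
    """Healthy white-matter group means: F_r=0.28, T2_f=672 us, T2_r=23.4 us."""
    return PoolParams.from_t2(0.28, 672.0, 23.4)


@pytest.fixture(scope="session")
def presets():
    return tissue_presets()


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def gm_spectrum(gm_params, schedule):
    return forward_zspectrum(gm_params, schedule)
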