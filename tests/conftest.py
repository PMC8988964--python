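import numpy as np
import pytest

from mdsfr import (
    AbsorptionParams,
    FiberGeometry,
    ScatteringParams,
    ScenarioConfig,
    default_library,
    make_calibration_set,
)


@pytest.fixture(scope="session")
def lib():
    return default_library()


@pytest.fixture(scope="session")
def geom():
    return FiberGeometry()


@pytest.fixture(scope="session")
def grid():
    return np.arange(450.0, 901.0, 2.0)


@pytest.fixture
def skin_truth():
    return ScatteringParams(a_800=1.8, b=1.25), AbsorptionParams(bvf=0.02, sto2=0.65)


@pytest.fixture
def clean_noiseless_cal(geom, lib):
    """A noise-free, uncontaminated calibration set (oracle conditions)."""
    cfg = ScenarioConfig(seed=0, noiseless=True, n_replicates=3)
    return make_calibration_set(cfg, geometry=geom, lib=lib)
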