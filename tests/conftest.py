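import numpy as np
import pytest

from rootfos import (
    ElasticParams,
    RadiusModelParams,
    build_spiral_geometry,
    make_sensor_layout,
)


@pytest.fixture(scope="session")
def geometry():
    return build_spiral_geometry()


@pytest.fixture(scope="session")
def layout(geometry):
    return make_sensor_layout(geometry)


@pytest.fixture(scope="session")
def elastic():
    return ElasticParams()


@pytest.fixture(scope="session")
def radius_params():
    return RadiusModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240229)
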