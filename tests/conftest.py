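import numpy as np
import pytest
from hypothesis import settings

from sonijnd import Direction, MLPConventions, Quadrant, quadrant_standard

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def conventions() -> MLPConventions:
    return MLPConventions()


@pytest.fixture
def standard_I():
    return quadrant_standard(Quadrant.I)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(params=list(Quadrant), ids=lambda q: q.name)
def each_quadrant(request) -> Quadrant:
    return request.param


@pytest.fixture(params=list(Direction), ids=lambda d: d.value)
def each_direction(request) -> Direction:
    return request.param
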