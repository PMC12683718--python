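import numpy as np
import pytest

from eldersim.behavior import BehaviorParams
from eldersim.environment import (
    DensityKernel,
    DistanceModel,
    StudyRegion,
    generate_facilities,
)
from eldersim.population import initialize_population, make_facilities


@pytest.fixture
def region():
    return StudyRegion(
        kernels=(
            DensityKernel(5.0, 6.0, 0.5, 1.8),
            DensityKernel(9.5, 5.0, 0.3, 2.2),
            DensityKernel(12.0, 8.0, 0.2, 1.5),
        )
    )


@pytest.fixture
def euclid():
    return DistanceModel("euclidean")


@pytest.fixture
def params():
    return BehaviorParams()


@pytest.fixture
def facilities(region):
    return make_facilities(generate_facilities(region, seed=42))


@pytest.fixture
def agents(region):
    return initialize_population(200, region=region, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
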