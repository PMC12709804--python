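import pytest

from basketess.types import BasketData, McmcSettings, PriorSpec, Scenario

# short chains for tests that only need rough posterior means
FAST = McmcSettings(iterations=3000, burn_in=1000, seed=0)


@pytest.fixture
def homogeneous_data() -> BasketData:
    return BasketData(["a", "b", "c", "d"], [30] * 4, [9, 9, 9, 9])


@pytest.fixture
def mixed_data() -> BasketData:
    return BasketData(["a", "b", "c", "d"], [30] * 4, [4, 5, 6, 14])


@pytest.fixture
def tiny_data() -> BasketData:
    return BasketData(["a", "b"], [10, 10], [3, 3])


@pytest.fixture
def flat_prior() -> PriorSpec:
    return PriorSpec(-2.19, 2.0, sigma2_shape=0.375, sigma2_scale=1.5)


@pytest.fixture
def null_scenario() -> Scenario:
    return Scenario((0.15,) * 4, (30,) * 4, label="null")
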