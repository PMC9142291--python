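import numpy as np
import pytest

from plsqr import (
    CompartmentState,
    ModelVariant,
    SmokingParameters,
    load_scenario,
)


@pytest.fixture(scope="session")
def paper_params() -> SmokingParameters:
    return SmokingParameters(a=0.04, b=0.23, c=0.3, d=0.2, e=0.4, f=0.25)


@pytest.fixture(scope="session")
def paper_initial() -> CompartmentState:
    return CompartmentState(P=0.60301, L=0.24000, S=0.10628, Q=0.03260, R=0.01811)


@pytest.fixture(scope="session")
def paper_scenario():
    return load_scenario("paper")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def random_params(rng: np.random.Generator) -> SmokingParameters:
    r = 10.0 ** rng.uniform(-3, 0, size=5)
    return SmokingParameters(
        a=float(r[0]), b=float(r[1]), c=float(r[2]), d=float(r[3]),
        e=float(rng.uniform(0, 1)), f=float(r[4]),
    )


def random_state(rng: np.random.Generator) -> CompartmentState:
    return CompartmentState(*map(float, rng.uniform(0.01, 2.0, size=5)))
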