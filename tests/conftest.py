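import numpy as np
import pytest

from adrgame import ParameterSet, printed_sets, sample_parameters


@pytest.fixture(scope="session")
def scen_a() -> ParameterSet:
    return printed_sets()["A"].params


@pytest.fixture(scope="session")
def scen_b() -> ParameterSet:
    return printed_sets()["B"].params


@pytest.fixture(scope="session")
def scen_c() -> ParameterSet:
    return printed_sets()["C"].params


@pytest.fixture(scope="session")
def valid_sets():
    """A reusable pool of random valid parameter sets (seeded)."""
    return [s.params for s in
            sample_parameters("any", seed=101, n=1000, max_draws=20_000_000)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def interior_states(rng: np.random.Generator, n: int, margin: float = 0.05):
    """Random states strictly inside the cube, away from the faces."""
    return rng.uniform(margin, 1 - margin, size=(n, 3))
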