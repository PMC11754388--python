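import numpy as np
import pytest

from regmsar.simulate import Sim1Design, Sim2Design, generate_sim1, generate_sim2


@pytest.fixture(scope="session")
def small_sim1():
    """A tiny time-invariant dataset for filter and IO tests."""
    return generate_sim1(Sim1Design(N=5, T=10, P=5, zero_rate=0.5, seed=123))


@pytest.fixture(scope="session")
def small_sim2():
    return generate_sim2(Sim2Design(N=5, T=10, seed=321))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
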