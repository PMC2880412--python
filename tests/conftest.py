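import numpy as np
import pytest

from abfold import Conformation, EnergyModel, fibonacci_sequence, load_fibonacci_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def fib_fixtures():
    return {f.label: f for f in load_fibonacci_fixtures()}


@pytest.fixture
def fib13():
    return fibonacci_sequence(6)


@pytest.fixture
def model13(fib13):
    return EnergyModel(fib13)


@pytest.fixture
def random_conf(rng):
    def make(n: int) -> Conformation:
        return Conformation.random(n, rng)

    return make
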