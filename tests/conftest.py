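import numpy as np
import pytest

from tbpscan import fixtures
from tbpscan.affinity import ModelParameters, default_parameters


@pytest.fixture(scope="session")
def template() -> ModelParameters:
    """Consensus seed template (sharp TATA PWM, unit coefficients)."""
    return ModelParameters.consensus_template()


@pytest.fixture(scope="session")
def calibrated() -> ModelParameters:
    """Parameters calibrated on the packaged marker tables (computed once)."""
    return default_parameters()


@pytest.fixture(scope="session")
def all_records():
    return fixtures.load_all_tables()


@pytest.fixture(scope="session")
def table7():
    return fixtures.load_table(7)


@pytest.fixture(scope="session")
def inserts():
    return fixtures.named_inserts()


def random_sequence(rng: np.random.Generator, length: int = 51) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
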