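import numpy as np
import pytest

from ctldyn.model import ModelParameters, load_params


@pytest.fixture(scope="session")
def act_only() -> ModelParameters:
    """Packaged best-fit parameters, adoptive transfer without costimulation."""
    return load_params("act_only")


@pytest.fixture(scope="session")
def act_mab() -> ModelParameters:
    """Packaged best-fit parameters, adoptive transfer plus anti-CD137."""
    return load_params("act_mab")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230517)
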