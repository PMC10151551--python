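import numpy as np
import pytest

from vitikin.simulate import (
    PedigreeEvent,
    PedigreeSpec,
    SimConfig,
    breed,
    simulate_founders,
)


@pytest.fixture(scope="session")
def family_panel():
    """Founders plus one clone, one selfed offspring and one outcross child.

    10,000 loci so kinship coefficients concentrate near their expectations.
    """
    config = SimConfig(n_founders=6, n_loci=10_000, seed=11)
    founders = simulate_founders(config)
    ped = PedigreeSpec(
        [
            PedigreeEvent("CLONE", "clone", ("F000",)),
            PedigreeEvent("SELF1", "self", ("F001",)),
            PedigreeEvent("CHILD", "cross", ("F002", "F003")),
            PedigreeEvent("SIB", "cross", ("F002", "F003")),
        ]
    )
    return breed(founders, ped, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
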