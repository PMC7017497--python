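import numpy as np
import pytest

from quantgut import simulate


@pytest.fixture(scope="session")
def default_study():
    """One seeded synthetic study at the default (study) conditions."""
    return simulate.generate_study(simulate.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def noise_free_study():
    """Same design with every noise source off: exact expected readouts."""
    cfg = simulate.SimulationConfig(seed=42).noise_free()
    return simulate.generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
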