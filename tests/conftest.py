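import numpy as np
import pytest

from vesselwave import synthesize


@pytest.fixture(scope="session")
def retinal():
    """Default retinal-scale scenario (38 Hz, 5.3 mm, dispersive flexural wave)."""
    movie, truth = synthesize.retinal_scenario(seed=1)
    return movie, truth


@pytest.fixture(scope="session")
def carotid():
    """Default carotid-scale scenario (500 Hz, 4 cm, both modes)."""
    walls, truth = synthesize.carotid_scenario(seed=2)
    return walls, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
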