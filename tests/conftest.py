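import numpy as np
import pytest

from vscreen import synthetic
from vscreen.sift import ResidueKey


@pytest.fixture(scope="session")
def panel():
    return synthetic.default_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_panel():
    """Small mixed panel: glycine (no side chain), serine (hydroxyl), histidine."""
    return (
        ResidueKey("A", 10, "GLY"),
        ResidueKey("A", 20, "SER"),
        ResidueKey("A", 30, "HIS"),
    )
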