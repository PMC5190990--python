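import numpy as np
import pytest

from vitisense.synthetic_data import VirtualCanopy, render_side_view


@pytest.fixture(scope="session")
def canopy_scene():
    """A mid-vigor rendered frame with ground-truth labels."""
    canopy = VirtualCanopy(vigor=1.5, seed=11)
    return render_side_view(canopy, width=192, height=192, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
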