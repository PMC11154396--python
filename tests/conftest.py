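import numpy as np
import pytest

from tilquant import SynthParams, simulate_slide


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale slide parameters used across tests (noise-free)."""
    return SynthParams(width=320, height=320, seed=42)


@pytest.fixture(scope="session")
def noise_free_slide(small_params):
    """One noise-free slide: (truth, seg prob map, det prob map)."""
    return simulate_slide(small_params, "fixture_slide")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
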