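import numpy as np
import pytest

from stpstrf.simulate import make_vocmod_stimulus


@pytest.fixture(scope="session")
def short_stim():
    """Six concatenated 3-s two-band vocalization-noise samples (T=1800)."""
    return make_vocmod_stimulus(n_samples=6, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
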