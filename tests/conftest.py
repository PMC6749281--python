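import numpy as np
import pytest

from fbcsp_select import BandSpec, SynthConfig, bandpass, generate_session


@pytest.fixture(scope="session")
def easy_session():
    """Default high-SNR synthetic session (100 trials/class, 18 channels)."""
    return generate_session(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def easy_broadband(easy_session):
    epochs, _ = easy_session
    return bandpass(epochs, BandSpec(0.5, 40.0))


@pytest.fixture(scope="session")
def small_session():
    """Cheap session for pipeline plumbing tests."""
    return generate_session(SynthConfig(seed=3, n_channels=10, trials_per_class=20))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
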