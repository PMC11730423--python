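import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass

from comsway.simulate import SimConfig, make_trial


@pytest.fixture(scope="session")
def short_trial():
    """A 30 s noisy synthetic trial at default narrow-stance conditions."""
    return make_trial(SimConfig(seed=1, duration=30.0))


@pytest.fixture(scope="session")
def clean_trial():
    """A 30 s noise-free synthetic trial (no sensor noise, bias or wobble)."""
    return make_trial(SimConfig(seed=2, duration=30.0), noise=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
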