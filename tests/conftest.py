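import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hsfocus import SceneSpec, render_stack

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_stack():
    """Noisy rendered pushbroom stack at reduced size, shared across tests."""
    return render_stack(SceneSpec(size=(48, 48), seed=5), n_frames=21, seed=5)


@pytest.fixture(scope="session")
def clean_stack():
    """Noise-free render: the center frame equals the scene exactly."""
    return render_stack(SceneSpec(size=(48, 48), seed=5), n_frames=21, detector=None)
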