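import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctlt.lung_extraction import run_extraction
from ctlt.phantom import PhantomSpec, generate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_phantom():
    """Noise-free default-resolution chest phantom with ground truth."""
    spec = PhantomSpec(seed=0)
    vol, truth = generate(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def default_extraction(default_phantom):
    _spec, vol, _truth = default_phantom
    return run_extraction(vol)


@pytest.fixture(scope="session")
def small_phantom():
    spec = PhantomSpec.small(seed=1)
    vol, truth = generate(spec)
    return spec, vol, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
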