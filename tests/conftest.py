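import pytest
from hypothesis import HealthCheck, settings

from turfscreen import SceneParams, generate_scene
from turfscreen.pipeline import StudyConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_scene():
    """Default scene rendered without sensor noise (seed fixed)."""
    return generate_scene(SceneParams(noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def noiseless_full_green_scene():
    """Noiseless scene whose canopy is entirely green."""
    return generate_scene(SceneParams(noise_sd=0.0, green_fraction=1.0, seed=13))


@pytest.fixture(scope="session")
def default_config():
    return StudyConfig()
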