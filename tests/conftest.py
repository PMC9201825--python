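import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scenes():
    """Ten small rendered scenes shared by the pipeline-level tests."""
    from wheatkit import SceneSpec, generate_scenes

    spec = SceneSpec(image_size=(96, 96), seed=7)
    return generate_scenes(spec, 10)
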