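import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def quick_scene_params(seed: int = 1, **overrides):
    """Reduced-density scene parameters for fast unit tests."""
    from quadvol.synthetic import SceneParams

    defaults = dict(seed=seed, point_density_per_m2=1.5e5, stem_count=120)
    defaults.update(overrides)
    return SceneParams(**defaults)
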