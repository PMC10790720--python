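import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """Small architecture for fast functional tests (not the training default)."""
    from rhizolen.models import ModelConfig

    return ModelConfig(
        in_size=(48, 32), channels=(4, 6, 8), decoder_channels=4,
        head_hidden=8, init_seed=0,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """16 automated-profile frames at reduced resolution for fast train tests."""
    import rhizolen as rl

    cam = rl.CameraProfile(name="tiny_cam", fov_mm=(25.0, 19.0), size_px=(184, 121),
                           depth_step_mm=18.75)
    spec = rl.automated_scene_spec(camera=cam)
    out = tmp_path_factory.mktemp("tiny_ds")
    index = rl.generate_dataset(16, spec, out, rng=np.random.default_rng(7))
    return index
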