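import numpy as np
import pytest
from hypothesis import HealthCheck, settings

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
    return np.random.default_rng(0)


@pytest.fixture
def marker():
    from spheretrack import default_marker

    return default_marker()


@pytest.fixture
def rig():
    from spheretrack import default_camera_rig

    return default_camera_rig()


@pytest.fixture
def identity_rig():
    """Camera rig with identity extrinsics (depth frame == world frame)."""
    from spheretrack import CameraRig, RigidTransform, build_lookup_table

    return CameraRig(
        lookup=build_lookup_table(350.0, (255.5, 255.5)),
        world_from_left=RigidTransform.identity(),
        left_from_depth=RigidTransform.identity(),
    )
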