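import numpy as np
import pytest

from ocumask import (
    Camera,
    SyntheticAssetSpec,
    TrajectorySpec,
    generate_assets,
    generate_sequence,
)


@pytest.fixture(scope="session")
def assets():
    return generate_assets(SyntheticAssetSpec(seed=7))


@pytest.fixture(scope="session")
def camera():
    return Camera()


@pytest.fixture(scope="session")
def sweep_sequence(assets):
    """Short zero-noise gaze sweep used by several fitting tests."""
    return generate_sequence(
        assets, TrajectorySpec(n_frames=12, motif="gaze_sweep", seed=1)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
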