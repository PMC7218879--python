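import numpy as np
import pytest

from skelact import Motion, SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_motion(rng):
    """A 20-frame, 5-joint random motion."""
    return Motion(frames=rng.normal(0, 10, size=(20, 5, 3)), motion_id="rand20")


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but learnable dataset: 3 classes x 6 motions, short clips."""
    cfg = SyntheticConfig(
        n_classes=3,
        motions_per_class=6,
        frame_range=(20, 40),
        seed=7,
    )
    return generate_dataset(cfg)
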