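import numpy as np
import pytest

from gazesim import CameraIntrinsics


@pytest.fixture
def intr() -> CameraIntrinsics:
    """The study-condition camera: wide 480x240 sensor, f = 240 px."""
    return CameraIntrinsics(width=480, height=240, focal_px=240.0, fovea_side=14)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
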