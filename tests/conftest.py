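import numpy as np
import pytest

from cmbeat import FrameStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_pair(rng):
    """Two independent 64x64 noise-texture frames (no relation to each other)."""
    return rng.uniform(0, 255, (64, 64)), rng.uniform(0, 255, (64, 64))


def make_stack(frames, frame_rate_hz=30.0, pixel_size_um=1.0):
    return FrameStack(
        frames=np.asarray(frames, dtype=float),
        frame_rate_hz=frame_rate_hz,
        pixel_size_um=pixel_size_um,
    )
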