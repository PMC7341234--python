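import sys
from pathlib import Path

import numpy as np
import pytest

from flockai import FrameSequence

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable


@pytest.fixture
def rng():
    return np.random.default_rng(20200626)


@pytest.fixture
def static_seq():
    """Three identical 10x10 frames at 25 fps."""
    frame = np.full((10, 10), 80, dtype=np.uint8)
    return FrameSequence(frames=np.stack([frame] * 3), frame_rate=25.0)


def make_sequence(frames, frame_rate=25.0, **kwargs):
    return FrameSequence(frames=np.stack(frames), frame_rate=frame_rate, **kwargs)
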