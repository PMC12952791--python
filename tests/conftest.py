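import numpy as np
import pytest

from ethokit.annotations import Ethogram
from ethokit.pose import KEYPOINT_NAMES, PoseSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pose(rng, n_frames=50, fps=30.0):
    pts = rng.uniform(50, 750, size=(n_frames, len(KEYPOINT_NAMES), 2))
    conf = rng.uniform(0.5, 1.0, size=(n_frames, len(KEYPOINT_NAMES)))
    return PoseSequence(pts, conf, fps=fps)


def random_track(rng, n=50, p=0.3, unlabeled=0.0):
    labels = (rng.random(n) < p).astype(np.int8)
    if unlabeled > 0:
        labels[rng.random(n) < unlabeled] = -1
    return Ethogram(labels)


@pytest.fixture
def pose_seq(rng):
    return random_pose(rng, n_frames=100)
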