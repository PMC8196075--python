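import numpy as np
import pytest

from strugglescope.kinematics import MobilitySeries


@pytest.fixture
def mobility_factory():
    """Build a MobilitySeries from per-point boolean frame flags."""

    def make(head=None, tail=None, fps=10.0):
        head = np.asarray(head, dtype=bool)
        tail = (
            np.asarray(tail, dtype=bool)
            if tail is not None
            else np.zeros_like(head)
        )
        mobile = np.stack([head, tail], axis=1)
        return MobilitySeries(
            point_names=["head_fiber", "tail_tip"],
            mobile=mobile,
            thresholds={"head_fiber": 1.0, "tail_tip": 1.0},
            fps=fps,
        )

    return make


def frames_to_flags(n_frames, mobile_frames):
    flags = np.zeros(n_frames, dtype=bool)
    flags[list(mobile_frames)] = True
    return flags
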