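import numpy as np
import pytest

from twinscan import MotionTrace, QCThresholds, default_protocol


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def protocol():
    return default_protocol()


@pytest.fixture
def thresholds():
    return QCThresholds()


def make_trace(rng, n_volumes=20, amp=0.1, run_label="snat1", subject_id="S1"):
    """A small random but well-behaved motion trace."""
    rot = np.cumsum(rng.normal(0, amp / 50.0, size=(n_volumes, 3)), axis=0)
    trans = np.cumsum(rng.normal(0, amp, size=(n_volumes, 3)), axis=0)
    return MotionTrace(
        subject_id=subject_id, run_label=run_label,
        rotations=rot, translations=trans,
    )


@pytest.fixture
def random_trace(rng):
    return make_trace(rng)
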