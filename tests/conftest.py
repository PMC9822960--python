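import numpy as np
import pytest

from myolight import (
    default_subject_params,
    demultiplex,
    make_gesture_protocol,
    simulate_gesture_session,
    slide_windows,
)

TOY_GESTURES = ("power", "pinch")


@pytest.fixture(scope="session")
def tiny_protocol():
    """Short two-gesture protocol (2 s rest / 2 s gesture, 3 reps)."""
    return make_gesture_protocol(2.0, 2.0, 3, TOY_GESTURES)


@pytest.fixture(scope="session")
def tiny_params():
    return default_subject_params(TOY_GESTURES, seed=7, noise_level=0.05)


@pytest.fixture(scope="session")
def tiny_session(tiny_protocol, tiny_params):
    return simulate_gesture_session(tiny_protocol, tiny_params, seed=11)


@pytest.fixture(scope="session")
def tiny_lmg_windows(tiny_session):
    rec = demultiplex(tiny_session.lmg)
    return slide_windows(rec, label_policy="strict")


def separable_windows(n_per_class=40, length=16, channels=8, noise=0.02, seed=0):
    """Two constant-level classes, linearly separable by window mean."""
    rng = np.random.default_rng(seed)
    y = np.array(["a", "b"] * n_per_class)
    x = np.where((y == "a")[:, None, None], 0.25, -0.25)
    x = x + noise * rng.standard_normal((2 * n_per_class, length, channels))
    return x.astype(np.float32), y
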