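import numpy as np
import pytest

import fretkinetics as fk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_state_scheme():
    """Symmetric two-state switcher, k12 = k21 = 0.2 /s."""
    return fk.KineticScheme(
        states=[fk.StateSpec("mid", 0.6, 0.03), fk.StateSpec("high", 0.9, 0.03)],
        rates=np.array([[0.0, 0.2], [0.2, 0.0]]),
    )


@pytest.fixture
def three_state_scheme():
    """Ergodic three-level scheme spanning the low/mid/high regimes."""
    return fk.KineticScheme(
        states=[
            fk.StateSpec("low", 0.1, 0.03),
            fk.StateSpec("mid", 0.6, 0.03),
            fk.StateSpec("high", 0.9, 0.03),
        ],
        rates=np.array([[0.0, 0.2, 0.0], [0.1, 0.0, 0.2], [0.0, 0.25, 0.0]]),
    )


@pytest.fixture
def cascade_scheme():
    """Irreversible cascade 0.9 -> 0.6 -> 0.1 (no reverse rates)."""
    return fk.KineticScheme(
        states=[
            fk.StateSpec("low", 0.1, 0.02),
            fk.StateSpec("mid", 0.6, 0.02),
            fk.StateSpec("high", 0.9, 0.02),
        ],
        rates=np.array([[0.0, 0.0, 0.0], [0.3, 0.0, 0.0], [0.0, 0.3, 0.0]]),
        initial_probs=np.array([0.0, 0.0, 1.0]),
    )


def make_ideal(levels_and_lengths, molecule_id="m0", frame_interval=0.2):
    """Build an IdealizedTrajectory from (level, n_frames) pairs."""
    segs, start = [], 0
    for level, n in levels_and_lengths:
        segs.append(fk.Segment(start, start + n, level))
        start += n
    return fk.IdealizedTrajectory(
        molecule_id=molecule_id, frame_interval=frame_interval, segments=segs
    )


@pytest.fixture
def ideal_factory():
    return make_ideal
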