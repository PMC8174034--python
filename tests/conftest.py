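import numpy as np
import pytest

from leverhold.core import BehavioralSession, Dataset, Group, UnitRecording
from leverhold.simulate import BehaviorParams, simulate_behavior


def make_session(
    durations_ms,
    gaps_ms=None,
    criterion_ms=1600,
    session_id="s1",
    mouse_id="m1",
    group=Group.AIR,
    first_onset_ms=1000.0,
    session_end_pad_ms=12_000.0,
):
    """Build a grid-aligned session from press durations and gaps."""
    durations = np.asarray(durations_ms, dtype=float)
    n = len(durations)
    if gaps_ms is None:
        gaps_ms = np.full(n, 5000.0)
    gaps = np.asarray(gaps_ms, dtype=float)
    onsets = np.empty(n)
    offsets = np.empty(n)
    t = first_onset_ms
    for i in range(n):
        onsets[i] = t
        offsets[i] = t + durations[i]
        t = offsets[i] + gaps[i]
    rewards = offsets[durations > criterion_ms]
    return BehavioralSession(
        session_id=session_id,
        mouse_id=mouse_id,
        group=group,
        criterion_ms=criterion_ms,
        press_onsets=onsets,
        press_offsets=offsets,
        reward_times=rewards,
        session_end_ms=offsets[-1] + session_end_pad_ms if n else session_end_pad_ms,
    )


@pytest.fixture(scope="session")
def default_session():
    """A realistic simulated session (~25% rewarded, ends at 60 rewards)."""
    return simulate_behavior(BehaviorParams(), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
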