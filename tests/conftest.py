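import numpy as np
import pytest

import lithowarn as lw


@pytest.fixture(scope="session")
def default_segments_60s():
    """Pure-label 500 ms windows from 60 s of each state, shipped defaults."""
    segments = []
    for i, state in enumerate(("idle", "stone", "tissue")):
        rec = lw.simulate_state_signal(state, 60.0, seed=42 + i)
        segments += lw.segment_recording(rec)
    return segments


@pytest.fixture(scope="session")
def short_segments():
    """Smaller pool (20 s per state) for faster protocol tests."""
    segments = []
    for i, state in enumerate(("idle", "stone", "tissue")):
        rec = lw.simulate_state_signal(state, 20.0, seed=7 + i)
        segments += lw.segment_recording(rec)
    return segments


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_recording(rng):
    n = 257
    return lw.Recording(
        samples=rng.normal(size=n) ** 2,
        labels=rng.integers(0, 3, size=n),
        sampling_rate_hz=100.0,
    )
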