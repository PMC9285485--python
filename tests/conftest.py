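import numpy as np
import pytest

from neoqc import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def short_recording(rng):
    """60-s, 9-channel band-limited noise recording at 250 Hz."""
    fs = 250.0
    n = int(60 * fs)
    data = rng.standard_normal((9, n)) * 20.0
    return Recording(data, fs)


def random_interval_set(rng, duration_s, fs, max_intervals=6, label="other"):
    """Random grid-aligned disjoint interval set for property tests."""
    from neoqc import Interval, IntervalSet

    n = int(duration_s * fs)
    k = rng.integers(0, max_intervals + 1)
    edges = np.sort(rng.choice(np.arange(n + 1), size=2 * k, replace=False))
    intervals = []
    for s, e in zip(edges[::2], edges[1::2]):
        if e > s:
            intervals.append(Interval(s / fs, e / fs, label))
    return IntervalSet(intervals)
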