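import numpy as np
import pytest

from fewt import Signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_signal(rng):
    return Signal(rng.standard_normal(1024), rate=256.0)


def brute_force_peaks(mag):
    """Independent local-maximum scan: both neighbours strictly smaller."""
    return [
        i
        for i in range(1, len(mag) - 1)
        if mag[i] > mag[i - 1] and mag[i] > mag[i + 1]
    ]


def random_segmentation(rng, max_internal=5):
    """A random admissible segmentation of [0, pi]."""
    n_internal = int(rng.integers(1, max_internal + 1))
    internal = np.sort(rng.uniform(0.15, np.pi - 0.15, size=n_internal))
    while np.any(np.diff(internal) < 0.1):
        internal = np.sort(rng.uniform(0.15, np.pi - 0.15, size=n_internal))
    boundaries = np.concatenate(([0.0], internal, [np.pi]))
    gaps = np.diff(boundaries)
    taus = np.array(
        [
            rng.uniform(0.05, 0.95) * min(gaps[i], gaps[i + 1]) / 2.0
            for i in range(n_internal)
        ]
    )
    return boundaries, taus
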