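import numpy as np
import pandas as pd
import pytest

from nonwear import EpochCountSeries, TriaxialRecording

T0 = pd.Timestamp("2020-01-06 00:00:00")


@pytest.fixture
def rng():
    return np.random.default_rng(20200106)


def make_recording(data, rate=100.0, start=T0):
    return TriaxialRecording(start, rate, np.asarray(data, dtype=float))


def constant_recording(minutes, vector=(0.0, 0.0, 1.0), rate=100.0, start=T0):
    n = int(minutes * 60 * rate)
    return make_recording(np.tile(np.asarray(vector, float), (n, 1)), rate, start)


def counts_from_axis(values, start=T0, epoch_length=60.0):
    """EpochCountSeries whose x-axis carries ``values`` (y, z zero)."""
    v = np.asarray(values)
    counts = np.zeros((v.shape[0], 3), dtype=np.int64)
    counts[:, 0] = v
    return EpochCountSeries(start, counts, epoch_length)


@pytest.fixture
def small_noise_recording(rng):
    """10 minutes of 100 Hz white noise at 10 mg per axis."""
    data = rng.normal(0, 0.010, (10 * 60 * 100, 3)) + np.array([0.0, 0.0, 1.0])
    return make_recording(data)
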