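import numpy as np
import pytest

from heatstrain.io_ingest import SampleStream, WearRecord


def make_stream(metric, timestamps, values):
    return SampleStream(metric, np.asarray(timestamps, float), np.asarray(values, float))


def minute_stream(metric, values, t0=0.0):
    """A 60-s cadence stream starting at t0."""
    values = np.asarray(values, float)
    return SampleStream(metric, t0 + 60.0 * np.arange(values.size), values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_record():
    """Two metrics over 10 minutes; enough for ingest/merge round-trips."""
    return WearRecord(
        "P900",
        "uuid-1",
        {
            "bbi": make_stream("bbi", np.arange(0, 600, 0.8), np.full(750, 800.0)),
            "steps": minute_stream("steps", [0, 0, 5, 12, 20, 18, 0, 0, 3, 1]),
        },
    )
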