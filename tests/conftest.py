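import numpy as np
import pytest

from dpcawin import Signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_signal():
    return Signal(samples=np.arange(1.0, 8.0), sample_rate=10.0,
                  label="A", source_id="short")


def make_signal(samples, label=None, rate=100.0, source_id="sig"):
    return Signal(samples=np.asarray(samples, dtype=float), sample_rate=rate,
                  label=label, source_id=source_id)


@pytest.fixture
def two_class_signals(rng):
    """Two labelled random signals, 1024 samples each."""
    return [
        make_signal(rng.standard_normal(1024), label="A", source_id="a0"),
        make_signal(rng.standard_normal(1024), label="B", source_id="b0"),
    ]
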