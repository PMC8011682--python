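import numpy as np
import pytest

from phasesync import FilterSpec, RawSeries

TR = 2.0


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def band():
    return FilterSpec(0.03, 0.07, 5)


@pytest.fixture
def make_sinusoid():
    """Factory for sinusoid RawSeries: amplitude * cos(2 pi f t + phase)."""

    def _make(freq_hz, n=210, tr=TR, amplitude=1.0, phase=0.0, label="sin"):
        t = np.arange(n) * tr
        return RawSeries(amplitude * np.cos(2 * np.pi * freq_hz * t + phase), tr, label)

    return _make
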