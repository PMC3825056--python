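import numpy as np
import pytest

from heartloc import Signal

RATE = 8000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone():
    """Factory: cosine tone with an integer number of periods."""

    def _tone(freq_hz=62.5, n=4096, amplitude=1.0, rate=RATE):
        cycles = freq_hz * n / rate
        assert abs(cycles - round(cycles)) < 1e-9, "pick an integer-period tone"
        t = np.arange(n) / rate
        return Signal(samples=amplitude * np.cos(2 * np.pi * freq_hz * t), rate=rate)

    return _tone


@pytest.fixture
def random_signal(rng):
    def _make(n=4096, rate=RATE):
        return Signal(samples=rng.standard_normal(n), rate=rate)

    return _make
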