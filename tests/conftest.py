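import numpy as np
import pytest

from tempocode.core_signals import Waveform


def make_tone(f_hz: float, duration: float = 1.0, fs: float = 8000.0) -> Waveform:
    t = np.arange(int(round(duration * fs))) / fs
    return Waveform(np.sin(2 * np.pi * f_hz * t), fs)


def autocorr_f0_oracle(w: Waveform, f_min: float, f_max: float) -> float:
    """Independent brute-force pitch oracle: peak of the raw waveform
    autocorrelation in the lag range [1/f_max, 1/f_min]."""
    x = w.samples - w.samples.mean()
    r = np.correlate(x, x, mode="full")[x.size - 1 :]
    fs = w.sample_rate
    lo = int(np.ceil(fs / f_max))
    hi = int(np.floor(fs / f_min))
    lag = lo + int(np.argmax(r[lo : hi + 1]))
    return fs / lag


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
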