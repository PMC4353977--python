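import numpy as np
import pytest

from thetanet.signal_io import Period, Session


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_session(rng):
    """Two-channel 10-s session at 1 kHz: an 8 Hz line in both + noise."""
    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    shared = np.cos(2 * np.pi * 8.0 * t)
    sig = np.vstack([
        5 * shared + 0.5 * rng.standard_normal(len(t)),
        4 * shared + 0.5 * rng.standard_normal(len(t)),
    ])
    timeline = [Period("Base", 0.0, 5.0), Period("Enc1", 5.0, 10.0)]
    return Session(sig, fs, ["MeA", "LS"], timeline)
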