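import numpy as np
import pytest

from dyadsync.ibi import BeatSeries, UniformIBISeries
from dyadsync.spectral import BandSpec, build_taper_bank


@pytest.fixture(scope="session")
def adult_band():
    return BandSpec(0.12, 0.40, "adult")


@pytest.fixture(scope="session")
def taper_bank():
    return build_taper_bank(window_samples=128, n_tapers=3, family="dpss")


@pytest.fixture
def regular_beats():
    """300 s of perfectly regular 800 ms beats."""
    return BeatSeries(times=np.arange(0.0, 300.0, 0.8))


def make_uniform(values, valid=None, rate=4.0):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.size, dtype=bool)
    return UniformIBISeries(values=values, valid_mask=np.asarray(valid, dtype=bool), rate=rate)


@pytest.fixture
def sinusoid_series():
    """300 s of 800 + 40 sin(2 pi 0.25 t) ms sampled at 4 Hz: band power 800 ms^2."""
    t = np.arange(1200) / 4.0
    return make_uniform(800.0 + 40.0 * np.sin(2 * np.pi * 0.25 * t))
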