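import numpy as np
import pytest

from hrvsym.rr_core import BeatSeries, RRSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def metronome_beats():
    """Perfectly regular 1-s beats over 5 minutes, all normal."""
    times = np.arange(0, 301_000, 1000.0)
    return BeatSeries(times, np.full(times.size, "N"), subject_id="metronome")


def make_rr(values, t0=0.0, label=None):
    values = np.asarray(values, dtype=float)
    starts = t0 + np.concatenate(([0.0], np.cumsum(values[:-1])))
    return RRSeries(rr=values, start_times=starts, window_label=label)


@pytest.fixture
def make_rr_series():
    return make_rr
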