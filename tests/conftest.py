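import numpy as np
import pandas as pd
import pytest

from arousalscore import FEATURE_NAMES
from arousalscore.io import Recording
from arousalscore.preprocess import SegmentPair
from arousalscore.io import ArousalEvent


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def sine_recording():
    """10 s, 200 Hz, 7 channels of a 10 Hz sine plus small noise."""
    fs = 200.0
    t = np.arange(int(10 * fs)) / fs
    gen = np.random.default_rng(0)
    chans = {
        lab: 50e-6 * np.sin(2 * np.pi * 10 * t) + 5e-6 * gen.standard_normal(t.size)
        for lab in ("C3", "C4", "O1", "O2", "F3", "F4", "chin")
    }
    return Recording(chans, fs=fs)


def make_pair(arousal, pre, fs=128.0, duration=None, onset=100.0):
    """Wrap per-signal arrays into a SegmentPair with a consistent event."""
    n = len(next(iter(arousal.values())))
    dur = duration if duration is not None else n / fs
    # short unit-test windows are tagged sham so event validation passes
    ev = ArousalEvent(onset=onset, duration=dur, is_sham=dur < 3.0)
    return SegmentPair(arousal=arousal, pre=pre, fs=fs, event=ev)


@pytest.fixture
def composite_pair(rng):
    """A 4-signal (C34/O12/F34/chin) pair of independent noise segments."""
    n = 512
    arousal = {s: rng.standard_normal(n) * 30e-6 for s in ("C34", "O12", "F34", "chin")}
    pre = {s: rng.standard_normal(n) * 20e-6 for s in ("C34", "O12", "F34", "chin")}
    return make_pair(arousal, pre)


def make_feature_frame(n, rng, stage="N2", level_effect=3.0, n_levels=5, prefix="ev"):
    """A synthetic feature table whose level signal lives in a few columns."""
    levels = np.tile(np.arange(n_levels), n // n_levels + 1)[:n]
    X = rng.standard_normal((n, len(FEATURE_NAMES)))
    X[:, 0] += level_effect * levels
    X[:, 1] += level_effect * (levels % 2)
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df.insert(0, "event_id", [f"{prefix}:{i}" for i in range(n)])
    df.insert(1, "recording", "recA")
    df.insert(2, "stage", stage)
    df.insert(3, "level", levels)
    df.insert(4, "onset_s", np.arange(n) * 60.0)
    df.insert(5, "duration_s", 9.0)
    return df
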