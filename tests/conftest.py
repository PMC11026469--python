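import numpy as np
import pytest

from holterhrv import BeatSeries, NNSeries, RecordingMeta


def series_from_labels(labels, spacing_ms=1000.0, **cols):
    """BeatSeries with equally spaced beats carrying the given labels."""
    n = len(labels)
    t = np.arange(n, dtype=float) * spacing_ms
    return BeatSeries(
        t_r=t, labels=np.array(list(labels), dtype="U1"),
        meta=RecordingMeta(duration_ms=float(t[-1]) if n else 0.0), **cols,
    )


def nn_from_rr(rr, start0=0.0, duration_ms=None):
    """Fully contiguous NNSeries with the given interval durations."""
    rr = np.asarray(rr, dtype=float)
    starts = start0 + np.concatenate(([0.0], np.cumsum(rr[:-1])))
    meta = RecordingMeta(duration_ms=duration_ms)
    return NNSeries(start_ms=starts, rr_ms=rr, n_excluded=0, meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
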