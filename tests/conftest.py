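import numpy as np
import pytest

from afrisk.ingest import BeatSeries, HourSegment


def series_from_rr(rr, labels=None, patient_id="T", start_day=1, start_hour=0.0):
    """BeatSeries with cumulative times reconstructed from RR (t[0] = 0)."""
    rr = np.asarray(rr, dtype=float)
    t = np.concatenate(([0.0], np.cumsum(rr[1:]) / 1000.0))
    if labels is None:
        labels = np.full(rr.size, "N", dtype="<U1")
    return BeatSeries(patient_id, t, rr, np.asarray(labels, dtype="<U1"),
                      start_day=start_day, start_hour=start_hour)


def segment_from_rr(rr, labels=None, index=0, patient_id="T", day=1):
    """Single HourSegment built directly from an RR sequence."""
    s = series_from_rr(rr, labels, patient_id)
    return HourSegment(patient_id, index, s.t, s.rr, s.labels, day=day)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
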