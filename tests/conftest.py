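"""Shared fixtures: small synthetic curves and events."""

import numpy as np
import pytest

from inclinegait.extraction import StanceEvent
from inclinegait.io import ParticipantMeta
from inclinegait.normalization import NormalizedCurve

#: body weight for which 1.0 body-weight fraction equals 735.75 N
WEIGHT_KG = 75.0


@pytest.fixture
def meta() -> ParticipantMeta:
    return ParticipantMeta(participant_id="P001", body_weight_kg=WEIGHT_KG)


def make_event(forces_n, start_ms=0, period_ms=10, **ids) -> StanceEvent:
    forces_n = np.asarray(forces_n, dtype=float)
    ts = start_ms + period_ms * np.arange(forces_n.size, dtype=np.int64)
    defaults = dict(participant_id="P001", foot="left", grade=0)
    defaults.update(ids)
    return StanceEvent(timestamps_ms=ts, forces_n=forces_n, **defaults)


def make_curve(values, **ids) -> NormalizedCurve:
    values = np.asarray(values, dtype=float)
    assert values.size == 100
    defaults = dict(
        participant_id="P001", foot="left", grade=0, start_ms=0, end_ms=990
    )
    defaults.update(ids)
    return NormalizedCurve(values=values, **defaults)


def m_curve(fz2=1.2, fz3=0.88, fz4=1.16, i2=25, i3=50, i4=75, edge=0.1) -> np.ndarray:
    """A clean piecewise-cosine M-curve with extrema exactly at i2/i3/i4."""
    x = np.arange(100, dtype=float)
    v = np.empty(100)

    def cos_seg(xs, x0, x1, y0, y1):
        t = (xs - x0) / (x1 - x0)
        return y0 + (y1 - y0) * 0.5 * (1 - np.cos(np.pi * t))

    v[: i2 + 1] = cos_seg(x[: i2 + 1], 0, i2, edge, fz2)
    v[i2 : i3 + 1] = cos_seg(x[i2 : i3 + 1], i2, i3, fz2, fz3)
    v[i3 : i4 + 1] = cos_seg(x[i3 : i4 + 1], i3, i4, fz3, fz4)
    v[i4:] = cos_seg(x[i4:], i4, 99, fz4, edge)
    return v


@pytest.fixture
def clean_m_curve() -> np.ndarray:
    return m_curve()
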