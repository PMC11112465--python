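"""The nine scalar parameters of one accepted stance curve.

Forces are fractions of body weight; slopes are in percent body weight per
percent stance duration (force enters the slope scaled by 100, consistent
with peak values near 1.2 but slope magnitudes near 5–11). All mean
windows are inclusive of both endpoint indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import CROSSING_FRACTION
from .extrema import ExtremaResult
from .normalization import NormalizedCurve


@dataclass
class StanceParameters:
    """Nine stance-curve parameters plus identifiers for one step.

    ``loading_slope``/``unloading_slope`` are None when the 80% crossing
    is degenerate (flagged); the other parameters are still reported.
    """

    step_id: str
    participant_id: str
    foot: str
    grade: int
    fz2: float
    fz3: float
    fz4: float
    fmean_stance: float
    fmean_load: float
    fmean_mid: float
    fmean_unload: float
    loading_slope: float | None
    unloading_slope: float | None
    flags: list[str] = field(default_factory=list)


def compute_means(
    curve: NormalizedCurve, ext: ExtremaResult
) -> tuple[float, float, float, float]:
    """Mean force over the whole stance and the load/mid/unload windows.

    Windows: [0, fz2_index], [fz2_index, fz4_index], [fz4_index, end],
    all inclusive.
    """
    if not ext.accepted:
        raise ValueError("means require an accepted extrema result")
    v = curve.values
    i2, i4 = ext.fz2_index, ext.fz4_index
    return (
        float(v.mean()),
        float(v[: i2 + 1].mean()),
        float(v[i2 : i4 + 1].mean()),
        float(v[i4:].mean()),
    )


def loading_slope(
    curve: NormalizedCurve, ext: ExtremaResult, *, crossing: float = CROSSING_FRACTION
) -> float | None:
    """Slope of the line from stance start to the first reading >= 80% of Fz2.

    The crossing search starts at index 0. Returns None (caller flags the
    stance) when the curve already starts at or above the crossing level.
    """
    if not ext.accepted:
        raise ValueError("slope requires an accepted extrema result")
    v = curve.values
    level = crossing * ext.fz2
    at_or_above = np.nonzero(v >= level)[0]
    i80 = int(at_or_above[0])
    if i80 == 0:
        return None
    return float((v[i80] - v[0]) * 100.0 / i80)


def unloading_slope(
    curve: NormalizedCurve, ext: ExtremaResult, *, crossing: float = CROSSING_FRACTION
) -> float | None:
    """Slope of the line from the first post-Fz4 reading < 80% of Fz4 to stance end.

    Returns None when no reading after Fz4 drops below the crossing level,
    or when the first such reading is the final sample.
    """
    if not ext.accepted:
        raise ValueError("slope requires an accepted extrema result")
    v = curve.values
    last = v.size - 1
    level = crossing * ext.fz4
    below = np.nonzero(v[ext.fz4_index + 1 :] < level)[0]
    if below.size == 0:
        return None
    iu = ext.fz4_index + 1 + int(below[0])
    if iu == last:
        return None
    return float((v[last] - v[iu]) * 100.0 / (last - iu))


def compute_parameters(
    curve: NormalizedCurve, ext: ExtremaResult, step_id: str
) -> StanceParameters:
    """Assemble all nine parameters for one accepted stance."""
    fmean_stance, fmean_load, fmean_mid, fmean_unload = compute_means(curve, ext)
    flags: list[str] = []
    ls = loading_slope(curve, ext)
    if ls is None:
        flags.append("loading_slope_undefined")
    us = unloading_slope(curve, ext)
    if us is None:
        flags.append("unloading_slope_undefined")
    # physiological guards: logged, not enforced
    if ls is not None and ls <= 0:
        flags.append("nonpositive_loading_slope")
    if us is not None and us >= 0:
        flags.append("nonnegative_unloading_slope")
    return StanceParameters(
        step_id=step_id,
        participant_id=curve.participant_id,
        foot=curve.foot,
        grade=curve.grade,
        fz2=ext.fz2,
        fz3=ext.fz3,
        fz4=ext.fz4,
        fmean_stance=fmean_stance,
        fmean_load=fmean_load,
        fmean_mid=fmean_mid,
        fmean_unload=fmean_unload,
        loading_slope=ls,
        unloading_slope=us,
        flags=flags,
    )
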