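"""Time and force normalization of stance events.

Each stance event is mapped to 100 equidistant samples covering the whole
stance (one per percent of stance duration) by fitting a natural cubic
spline — second derivative zero at both ends — to the event's raw
(timestamp, force) points and evaluating it on the uniform grid. Forces
are expressed as a fraction of body weight (1.0 = body weight), so peak
values above 1 are expected during load-bearing.

A Gaussian-smoothed copy (sigma = 3, kernel size 7) is produced solely to
localize extremum candidates; parameter values are always read from the
unfiltered curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .constants import GAUSSIAN_KERNEL_SIZE, GAUSSIAN_SIGMA, GRAVITY_MS2, N_POINTS
from .extraction import StanceEvent
from .io import ParticipantMeta

#: Minimum number of knots for a cubic spline fit.
MIN_SPLINE_SAMPLES = 4


@dataclass
class NormalizedCurve:
    """100-sample body-weight-normalized stance curve; index j is stance fraction j/99."""

    values: np.ndarray
    participant_id: str
    foot: str
    grade: int
    start_ms: int
    end_ms: int

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms


@dataclass
class FilteredCurve:
    """Gaussian-smoothed copy of a NormalizedCurve (same index convention)."""

    values: np.ndarray
    parent: NormalizedCurve = field(repr=False)


def normalize_curve(
    event: StanceEvent,
    meta: ParticipantMeta,
    *,
    n_points: int = N_POINTS,
    gravity: float = GRAVITY_MS2,
) -> NormalizedCurve | None:
    """Fit a natural cubic spline to the event and resample to ``n_points``.

    The spline is fitted on the true (possibly non-uniform) timestamps, so
    tolerated dropouts and sub-threshold gap samples are bridged naturally.
    Query times span [start_ms, end_ms] inclusive. Negative spline
    excursions are clamped to zero.

    Returns None for events with fewer than four samples (too few knots
    for a cubic fit); callers record this as a rejection, not an error.
    """
    if len(event) < MIN_SPLINE_SAMPLES:
        return None
    weight_n = meta.body_weight_kg * gravity
    spline = CubicSpline(
        event.timestamps_ms.astype(np.float64),
        event.forces_n / weight_n,
        bc_type="natural",
    )
    query = np.linspace(event.start_ms, event.end_ms, n_points)
    values = np.clip(spline(query), 0.0, None)
    return NormalizedCurve(
        values=values,
        participant_id=event.participant_id,
        foot=event.foot,
        grade=event.grade,
        start_ms=event.start_ms,
        end_ms=event.end_ms,
    )


def gaussian_kernel(
    sigma: float = GAUSSIAN_SIGMA, size: int = GAUSSIAN_KERNEL_SIZE
) -> np.ndarray:
    """Sampled Gaussian kernel of odd ``size``, normalized to sum 1."""
    if size % 2 != 1:
        raise ValueError("kernel size must be odd")
    k = np.arange(size) - size // 2
    w = np.exp(-(k.astype(float) ** 2) / (2.0 * sigma**2))
    return w / w.sum()


def gaussian_filter_curve(
    curve: NormalizedCurve,
    *,
    sigma: float = GAUSSIAN_SIGMA,
    size: int = GAUSSIAN_KERNEL_SIZE,
) -> FilteredCurve:
    """Smooth a normalized curve with the sampled-Gaussian kernel.

    At the boundaries the kernel is truncated to valid indices and
    renormalized, so constants are preserved everywhere.
    """
    values = smooth(curve.values, sigma=sigma, size=size)
    return FilteredCurve(values=values, parent=curve)


def smooth(values: np.ndarray, *, sigma: float = GAUSSIAN_SIGMA, size: int = GAUSSIAN_KERNEL_SIZE) -> np.ndarray:
    """Truncate-and-renormalize Gaussian smoothing of a 1-D array."""
    w = gaussian_kernel(sigma, size)
    num = np.convolve(values, w, mode="same")
    den = np.convolve(np.ones_like(values), w, mode="same")
    return num / den
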