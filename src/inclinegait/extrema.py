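"""Locating Fz2/Fz3/Fz4 on the smoothed stance curve.

The characteristic M-curve has two force maxima (Fz2, Fz4) separated by
one minimum (Fz3). Sensor jitter can produce several ambiguous local
extrema, so candidates are found on the Gaussian-filtered curve and, if
ambiguity remains, disambiguated by a four-strategy cascade applied in
order:

1. time plausibility — candidates within the first or last 10 indices are
   eliminated;
2. pool filtering — same-polarity candidates within 5 indices of each
   other form a pool and only the highest-force maximum / lowest-force
   minimum survives;
3. monotony check — candidates without a strictly monotone rise/fall over
   5 indices on both sides are eliminated;
4. monotony grace — if step 3 left fewer than 2 maxima or fewer than 1
   minimum, its casualties are reinstated in descending order of their
   achieved monotony distance until the target count is restored.

Each strategy runs only while the candidate set is still inconclusive.
A stance is accepted only if exactly two maxima and one minimum survive
with the minimum strictly between the maxima; the surviving indices are
then re-applied to the unfiltered normalized curve to read the values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import EDGE_MARGIN, MONOTONY_SPAN, POOL_SPAN
from .normalization import FilteredCurve, NormalizedCurve


@dataclass(frozen=True)
class ExtremumCandidate:
    index: int
    polarity: str  # "max" | "min"
    filtered_value: float
    monotony_distance: int


@dataclass
class ExtremaResult:
    status: str  # "accepted" | "rejected"
    reason: str | None = None  # "candidate_count" | "ordering"
    fz2_index: int | None = None
    fz3_index: int | None = None
    fz4_index: int | None = None
    fz2: float | None = None
    fz3: float | None = None
    fz4: float | None = None

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def _monotony_distance(values: np.ndarray, i: int, polarity: str, span: int) -> int:
    """Largest d <= span with strict monotony on both sides of index i.

    Strictly rising toward / falling away from a maximum; mirrored for a
    minimum. Runs truncated by the curve boundary cap the distance at the
    available length.
    """
    n = values.size
    sign = 1.0 if polarity == "max" else -1.0
    left = 0
    while left < span and i - left - 1 >= 0 and sign * values[i - left - 1] < sign * values[i - left]:
        left += 1
    right = 0
    while right < span and i + right + 1 < n and sign * values[i + right + 1] < sign * values[i + right]:
        right += 1
    return min(left, right)


def find_candidates(
    filtered: FilteredCurve | np.ndarray, *, span: int = MONOTONY_SPAN
) -> list[ExtremumCandidate]:
    """Strict local extrema of the filtered curve, interior indices only.

    Index i is a maximum candidate iff f[i] > f[i-1] and f[i] > f[i+1]
    (plateau points are never candidates), mirrored for minima.
    """
    v = filtered.values if isinstance(filtered, FilteredCurve) else np.asarray(filtered)
    out: list[ExtremumCandidate] = []
    for i in range(1, v.size - 1):
        if v[i] > v[i - 1] and v[i] > v[i + 1]:
            pol = "max"
        elif v[i] < v[i - 1] and v[i] < v[i + 1]:
            pol = "min"
        else:
            continue
        out.append(
            ExtremumCandidate(
                index=i,
                polarity=pol,
                filtered_value=float(v[i]),
                monotony_distance=_monotony_distance(v, i, pol, span),
            )
        )
    return out


def _is_conclusive(candidates: list[ExtremumCandidate]) -> bool:
    maxima = sorted(c.index for c in candidates if c.polarity == "max")
    minima = [c.index for c in candidates if c.polarity == "min"]
    return (
        len(maxima) == 2
        and len(minima) == 1
        and maxima[0] < minima[0] < maxima[1]
    )


def _pool_filter(candidates: list[ExtremumCandidate], span: int) -> list[ExtremumCandidate]:
    """Single-linkage clustering of same-polarity candidates with index
    gaps <= span; keeps the best per pool (ties -> earlier index)."""
    survivors: list[ExtremumCandidate] = []
    for polarity in ("max", "min"):
        group = sorted(
            (c for c in candidates if c.polarity == polarity), key=lambda c: c.index
        )
        pool: list[ExtremumCandidate] = []
        sign = 1.0 if polarity == "max" else -1.0

        def flush() -> None:
            if pool:
                survivors.append(
                    max(pool, key=lambda c: (sign * c.filtered_value, -c.index))
                )

        for c in group:
            if pool and c.index - pool[-1].index > span:
                flush()
                pool = []
            pool.append(c)
        flush()
    return sorted(survivors, key=lambda c: c.index)


def apply_cascade(
    candidates: list[ExtremumCandidate],
    filtered: FilteredCurve | np.ndarray | None = None,
    *,
    edge_margin: int = EDGE_MARGIN,
    pool_span: int = POOL_SPAN,
    monotony_span: int = MONOTONY_SPAN,
    n_points: int | None = None,
) -> list[ExtremumCandidate]:
    """Run the disambiguation cascade; returns the surviving candidates.

    The cascade is skipped entirely when the input is already conclusive,
    and stops as soon as a strategy renders it conclusive. Deterministic:
    all ties break toward the earlier index.
    """
    if n_points is None:
        if filtered is not None:
            v = filtered.values if isinstance(filtered, FilteredCurve) else np.asarray(filtered)
            n_points = int(v.size)
        else:
            n_points = 100
    survivors = list(candidates)
    if _is_conclusive(survivors):
        return survivors

    # (1) time plausibility: drop candidates in the first/last `edge_margin` indices
    survivors = [
        c for c in survivors if edge_margin <= c.index <= n_points - 1 - edge_margin
    ]
    if _is_conclusive(survivors):
        return survivors

    # (2) pool filtering
    survivors = _pool_filter(survivors, pool_span)
    if _is_conclusive(survivors):
        return survivors

    # (3) monotony check
    kept = [c for c in survivors if c.monotony_distance >= monotony_span]
    dropped = [c for c in survivors if c.monotony_distance < monotony_span]
    survivors = kept
    if _is_conclusive(survivors):
        return survivors

    # (4) monotony grace: reinstate casualties of (3), best monotony first;
    # ties broken by the stronger filtered force (the more plausible
    # extremum), then by the earlier index
    for polarity, target in (("max", 2), ("min", 1)):
        have = sum(1 for c in survivors if c.polarity == polarity)
        if have >= target:
            continue
        sign = 1.0 if polarity == "max" else -1.0
        pool = sorted(
            (c for c in dropped if c.polarity == polarity),
            key=lambda c: (-c.monotony_distance, -sign * c.filtered_value, c.index),
        )
        survivors.extend(pool[: target - have])
    return sorted(survivors, key=lambda c: c.index)


def finalize(
    candidates: list[ExtremumCandidate],
    normalized: NormalizedCurve,
    *,
    require_ordering: bool = True,
) -> ExtremaResult:
    """Accept or reject the stance and re-read values from the unfiltered curve.

    Accepted iff exactly two maximum candidates and one minimum candidate
    survive and (by convention, toggleable) the minimum lies strictly
    between the maxima. Values are the unfiltered normalized forces at the
    exact surviving indices — no local re-search.
    """
    maxima = sorted((c.index for c in candidates if c.polarity == "max"))
    minima = [c.index for c in candidates if c.polarity == "min"]
    if len(maxima) != 2 or len(minima) != 1:
        return ExtremaResult(status="rejected", reason="candidate_count")
    if require_ordering and not (maxima[0] < minima[0] < maxima[1]):
        return ExtremaResult(status="rejected", reason="ordering")
    v = normalized.values
    i2, i3, i4 = maxima[0], minima[0], maxima[1]
    return ExtremaResult(
        status="accepted",
        fz2_index=i2,
        fz3_index=i3,
        fz4_index=i4,
        fz2=float(v[i2]),
        fz3=float(v[i3]),
        fz4=float(v[i4]),
    )


def locate_extrema(
    normalized: NormalizedCurve,
    filtered: FilteredCurve,
    *,
    require_ordering: bool = True,
) -> ExtremaResult:
    """Full candidate → cascade → finalize chain for one stance."""
    cands = find_candidates(filtered)
    survivors = apply_cascade(cands, filtered)
    return finalize(survivors, normalized, require_ordering=require_ordering)
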