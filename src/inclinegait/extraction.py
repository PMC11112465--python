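"""Stance-event segmentation from raw force series.

A stance event is a maximal run of force readings strictly above the 30 N
threshold. Runs of up to three consecutive "missing values" — absent
timestamps (recording dropouts) and sub-threshold readings alike — are
tolerated inside an event; four or more terminate it. Candidates shorter
than 300 ms or longer than 2000 ms (first to last retained sample,
inclusive bounds) are discarded and logged.

Events always start and end on an above-threshold sample: tolerated gap
samples touching a boundary are trimmed. Sub-threshold samples inside a
tolerated gap are retained in the event's sample list (the spline later
treats them as ordinary knots); absent timestamps stay absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    FORCE_THRESHOLD_N,
    GAP_TOLERANCE,
    MAX_STANCE_MS,
    MIN_STANCE_MS,
)
from .io import RawForceSeries


@dataclass
class StanceEvent:
    """A contiguous above-threshold segment of one raw series."""

    participant_id: str
    foot: str
    grade: int
    timestamps_ms: np.ndarray
    forces_n: np.ndarray

    @property
    def start_ms(self) -> int:
        return int(self.timestamps_ms[0])

    @property
    def end_ms(self) -> int:
        return int(self.timestamps_ms[-1])

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms

    def __len__(self) -> int:
        return int(self.timestamps_ms.size)


@dataclass(frozen=True)
class Exclusion:
    """One discarded stance candidate with the reason for its exclusion."""

    participant_id: str
    foot: str
    grade: int
    start_ms: int
    end_ms: int
    reason: str  # "too_short" | "too_long"


def detect_stances(
    series: RawForceSeries,
    *,
    threshold_n: float = FORCE_THRESHOLD_N,
    gap_tolerance: int = GAP_TOLERANCE,
    min_duration_ms: float = MIN_STANCE_MS,
    max_duration_ms: float = MAX_STANCE_MS,
) -> tuple[list[StanceEvent], list[Exclusion]]:
    """Segment stance events from one raw series.

    Returns time-ordered, non-overlapping events plus an exclusion log of
    duration-filtered candidates. "Above threshold" is strict (a reading of
    exactly ``threshold_n`` counts as below). An empty series yields an
    empty result.
    """
    ts = series.timestamps_ms
    fs = series.forces_n
    period = 1000.0 / series.nominal_rate_hz

    events: list[StanceEvent] = []
    exclusions: list[Exclusion] = []

    def close(first: int, last_above: int) -> None:
        """Finish the candidate spanning sample indices [first, last_above]."""
        duration = float(ts[last_above] - ts[first])
        if duration < min_duration_ms:
            reason = "too_short"
        elif duration > max_duration_ms:
            reason = "too_long"
        else:
            events.append(
                StanceEvent(
                    participant_id=series.participant_id,
                    foot=series.foot,
                    grade=series.grade,
                    timestamps_ms=ts[first : last_above + 1].copy(),
                    forces_n=fs[first : last_above + 1].copy(),
                )
            )
            return
        exclusions.append(
            Exclusion(
                participant_id=series.participant_id,
                foot=series.foot,
                grade=series.grade,
                start_ms=int(ts[first]),
                end_ms=int(ts[last_above]),
                reason=reason,
            )
        )

    first: int | None = None  # index of the event's first (above) sample
    last_above: int = -1  # index of the most recent above-threshold sample
    bad_run: int = 0  # consecutive missing/sub-threshold samples so far

    n = ts.size
    for i in range(n):
        if first is not None and i > 0:
            # absent timestamps between sample i-1 and i count against the
            # tolerance like sub-threshold readings do
            missing = int(round((ts[i] - ts[i - 1]) / period)) - 1
            if missing > 0:
                bad_run += missing
                if bad_run > gap_tolerance:
                    close(first, last_above)
                    first, bad_run = None, 0
        above = fs[i] > threshold_n
        if above:
            if first is None:
                first = i
            last_above = i
            bad_run = 0
        elif first is not None:
            bad_run += 1
            if bad_run > gap_tolerance:
                close(first, last_above)
                first, bad_run = None, 0
    if first is not None:
        close(first, last_above)
    return events, exclusions
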