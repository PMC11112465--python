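"""Reading and writing insole force sessions and tabular outputs.

A raw session file holds one participant's recordings as delimited text:
two metadata header lines (participant id and body weight) followed by a
CSV table with one row per retained sample. Dropped samples are simply
absent rows; timestamps are integer milliseconds. Forces are stored in
Newtons; conversion to body-weight fraction happens only during curve
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import NOMINAL_RATE_HZ, PARAMETER_NAMES

logger = logging.getLogger(__name__)

RAW_COLUMNS = ["participant_id", "foot", "grade_percent", "timestamp_ms", "force_n"]

GROUND_TRUTH_COLUMNS = [
    "step_id",
    "participant_id",
    "foot",
    "grade",
    "start_ms",
    "end_ms",
    *PARAMETER_NAMES,
]


class SessionFormatError(ValueError):
    """Raised when a raw session file violates the format contract."""


@dataclass(frozen=True)
class ParticipantMeta:
    """Participant-level metadata; body weight is the normalization constant."""

    participant_id: str
    body_weight_kg: float
    height_cm: float | None = None
    age_years: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if not self.body_weight_kg > 0:
            raise ValueError(f"body weight must be positive, got {self.body_weight_kg}")


@dataclass
class RawForceSeries:
    """One foot's total vertical force recording at one treadmill grade.

    ``timestamps_ms`` are strictly increasing integer milliseconds; gaps
    wider than the nominal sampling period represent dropped samples.
    """

    participant_id: str
    foot: str  # "left" | "right"
    grade: int  # treadmill slope, percent
    timestamps_ms: np.ndarray
    forces_n: np.ndarray
    nominal_rate_hz: float = NOMINAL_RATE_HZ

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=np.int64)
        self.forces_n = np.asarray(self.forces_n, dtype=np.float64)
        if self.timestamps_ms.shape != self.forces_n.shape:
            raise ValueError("timestamps and forces must have equal length")
        if self.timestamps_ms.size > 1 and np.any(np.diff(self.timestamps_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.forces_n < 0):
            raise ValueError("negative force reading in series")

    def __len__(self) -> int:
        return int(self.timestamps_ms.size)


def write_session(
    meta: ParticipantMeta, series: Sequence[RawForceSeries], path: str | Path
) -> None:
    """Write one participant's raw session to ``path``."""
    path = Path(path)
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "foot": s.foot,
                    "grade_percent": s.grade,
                    "timestamp_ms": s.timestamps_ms,
                    "force_n": s.forces_n,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=RAW_COLUMNS)
    with path.open("w") as fh:
        fh.write("#inclinegait-raw-v1\n")
        fh.write(f"#participant_id={meta.participant_id}\n")
        fh.write(f"#body_weight_kg={meta.body_weight_kg!r}\n")
        table.to_csv(fh, index=False)


def read_session(path: str | Path) -> tuple[ParticipantMeta, list[RawForceSeries]]:
    """Read a raw session file.

    Returns the participant metadata and one :class:`RawForceSeries` per
    (foot, grade) present, in file order. Unknown columns are ignored with
    a logged warning; format violations raise :class:`SessionFormatError`
    naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, str] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            if "=" in line:
                key, _, value = line[1:].strip().partition("=")
                header[key] = value
    if "body_weight_kg" not in header:
        raise SessionFormatError(f"{path}: missing body_weight_kg header")
    meta = ParticipantMeta(
        participant_id=header.get("participant_id", path.stem),
        body_weight_kg=float(header["body_weight_kg"]),
    )

    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    unknown = [c for c in table.columns if c not in RAW_COLUMNS]
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path, unknown)
        table = table.drop(columns=unknown)
    missing = [c for c in RAW_COLUMNS if c not in table.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing columns {missing}")

    neg = np.nonzero(table["force_n"].to_numpy() < 0)[0]
    if neg.size:
        # +2 for the CSV header row, +n_header for metadata lines, 1-based
        row = int(neg[0]) + n_header + 2
        raise SessionFormatError(f"{path}: negative force at line {row}")

    series: list[RawForceSeries] = []
    for (foot, grade), chunk in table.groupby(["foot", "grade_percent"], sort=False):
        ts = chunk["timestamp_ms"].to_numpy(dtype=np.int64)
        if ts.size > 1 and np.any(np.diff(ts) <= 0):
            bad = int(np.nonzero(np.diff(ts) <= 0)[0][0])
            row = int(chunk.index[bad + 1]) + n_header + 2
            raise SessionFormatError(f"{path}: non-monotone timestamp at line {row}")
        series.append(
            RawForceSeries(
                participant_id=meta.participant_id,
                foot=str(foot),
                grade=int(grade),
                timestamps_ms=ts,
                forces_n=chunk["force_n"].to_numpy(dtype=np.float64),
            )
        )
    return meta, series


def parameters_to_frame(records: Iterable) -> pd.DataFrame:
    """Convert StanceParameters records to a tidy DataFrame (one row/step)."""
    rows = []
    for r in records:
        rows.append(
            {
                "step_id": r.step_id,
                "participant_id": r.participant_id,
                "foot": r.foot,
                "grade": r.grade,
                **{name: getattr(r, name) for name in PARAMETER_NAMES},
                "flags": ";".join(r.flags),
            }
        )
    columns = ["step_id", "participant_id", "foot", "grade", *PARAMETER_NAMES, "flags"]
    return pd.DataFrame(rows, columns=columns)


def write_parameters_table(records: Iterable, path: str | Path) -> None:
    """Write per-step stance parameters as CSV; empty input → header only.

    Floats are written at full round-trip precision.
    """
    frame = records if isinstance(records, pd.DataFrame) else parameters_to_frame(records)
    frame.to_csv(Path(path), index=False, float_format=None)


def read_parameters_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), float_precision="round_trip")
    if "flags" in frame.columns:
        frame["flags"] = frame["flags"].fillna("")
    return frame


def write_ground_truth(records: Iterable, path: str | Path) -> None:
    """Write the generator's ground-truth sidecar table."""
    rows = [
        {
            "step_id": r.step_id,
            "participant_id": r.participant_id,
            "foot": r.foot,
            "grade": r.grade,
            "start_ms": r.start_ms,
            "end_ms": r.end_ms,
            **{name: getattr(r, name) for name in PARAMETER_NAMES},
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS).to_csv(Path(path), index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), float_precision="round_trip")
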