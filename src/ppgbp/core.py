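"""Blood-pressure domain primitives.

Types for single BP readings, 24-hour ambulatory recordings and paired
PPG/BP observations, plus the small set of scalar computations the rest of
the package is built on: the mean-arterial-pressure (MAP) approximation,
the average-real-variability (ARV) index, its standard-deviation baseline,
and the recording-quality filter used to select technically adequate
ambulatory recordings.

Units: pressures are mmHg, timestamps are minutes since midnight in
[0, 1440), PPG levels are arbitrary units (a.u.).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BPReading",
    "Schedule",
    "AmbulatoryRecording",
    "BPSeries",
    "PairedObservation",
    "compute_map",
    "average_real_variability",
    "sd_variability",
    "recording_quality",
    "passes_quality",
    "QUALITY_THRESHOLD",
    "write_recordings",
    "read_recordings",
]

MINUTES_PER_DAY = 1440

#: Minimum fraction of valid readings for a recording of "good technical
#: quality". The comparison is strict: exactly 0.70 fails.
QUALITY_THRESHOLD = 0.70


def compute_map(sbp: float, dbp: float) -> float:
    """Mean arterial pressure from systolic and diastolic pressure.

    MAP = (2*DBP + SBP) / 3, the standard one-third-pulse-pressure
    approximation. Requires ``sbp > dbp > 0`` and finite inputs; the result
    lies strictly between DBP and SBP.
    """
    sbp = float(sbp)
    dbp = float(dbp)
    if not (math.isfinite(sbp) and math.isfinite(dbp)):
        raise ValueError("compute_map requires finite pressures")
    if dbp <= 0:
        raise ValueError(f"diastolic pressure must be positive, got {dbp}")
    if sbp <= dbp:
        raise ValueError(
            f"systolic pressure must exceed diastolic (got sbp={sbp} <= dbp={dbp})"
        )
    return (2.0 * dbp + sbp) / 3.0


@dataclass(frozen=True)
class BPReading:
    """One timestamped blood-pressure reading with a validity flag."""

    timestamp: float  # minutes since midnight, [0, 1440)
    sbp: float
    dbp: float
    valid: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.timestamp < MINUTES_PER_DAY:
            raise ValueError(f"timestamp {self.timestamp} outside [0, 1440)")
        if self.valid:
            if not (math.isfinite(self.sbp) and math.isfinite(self.dbp)):
                raise ValueError("valid reading requires finite pressures")
            if not (self.sbp > self.dbp > 0):
                raise ValueError(
                    f"valid reading requires sbp > dbp > 0, got {self.sbp}/{self.dbp}"
                )

    @property
    def map(self) -> float:
        return compute_map(self.sbp, self.dbp)


@dataclass(frozen=True)
class Schedule:
    """Ambulatory sampling plan: denser readings in the day window.

    Defaults follow the common 24-hour monitor programming of one reading
    every 15 minutes between 06:00 and 22:59 and every 30 minutes at night.
    """

    day_interval_min: int = 15
    night_interval_min: int = 30
    day_start_min: int = 6 * 60  # 06:00
    night_start_min: int = 23 * 60  # 23:00

    def __post_init__(self) -> None:
        if self.day_interval_min <= 0 or self.night_interval_min <= 0:
            raise ValueError("sampling intervals must be positive")
        if not 0 <= self.day_start_min < self.night_start_min < MINUTES_PER_DAY:
            raise ValueError("day window bounds must satisfy 0 <= start < end < 1440")

    def is_day(self, timestamp: float) -> bool:
        return self.day_start_min <= timestamp < self.night_start_min

    def slots(self) -> list[float]:
        """All scheduled reading times in one day, sorted by time of day."""
        times: list[float] = []
        # night segment before the day window (00:00 .. day_start)
        t = 0.0
        while t < self.day_start_min:
            times.append(t)
            t += self.night_interval_min
        t = float(self.day_start_min)
        while t < self.night_start_min:
            times.append(t)
            t += self.day_interval_min
        t = float(self.night_start_min)
        while t < MINUTES_PER_DAY:
            times.append(t)
            t += self.night_interval_min
        return times


@dataclass
class AmbulatoryRecording:
    """A subject's scheduled sequence of 24-hour BP readings."""

    subject_id: str
    readings: list[BPReading]
    schedule: Schedule = field(default_factory=Schedule)

    def __post_init__(self) -> None:
        ts = [r.timestamp for r in self.readings]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("readings must be strictly ordered by timestamp")

    @property
    def n_scheduled(self) -> int:
        return len(self.readings)

    @property
    def n_valid(self) -> int:
        return sum(r.valid for r in self.readings)

    def valid_readings(self) -> list[BPReading]:
        return [r for r in self.readings if r.valid]


@dataclass(frozen=True)
class BPSeries:
    """An ordered series of valid pressure values for variability analysis."""

    values: tuple[float, ...]

    def __init__(self, values: Iterable[float]) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in values))

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PairedObservation:
    """One averaged PPG level with its simultaneous reference BP readings."""

    ppg: float  # arbitrary units
    sbp: float
    dbp: float
    map: float

    def __post_init__(self) -> None:
        if not self.ppg > 0:
            raise ValueError(f"PPG level must be positive, got {self.ppg}")
        expected = compute_map(self.sbp, self.dbp)
        if abs(self.map - expected) > 1e-9:
            raise ValueError(
                f"map={self.map} inconsistent with (2*dbp + sbp)/3 = {expected}"
            )


def _as_values(series: BPSeries | Sequence[float] | np.ndarray) -> np.ndarray:
    vals = np.asarray(series.values if isinstance(series, BPSeries) else series, float)
    if vals.ndim != 1:
        raise ValueError("BP series must be one-dimensional")
    if not np.all(np.isfinite(vals)):
        raise ValueError("BP series must be finite")
    return vals


def average_real_variability(series: BPSeries | Sequence[float]) -> float:
    """Average real variability (ARV) of an ordered BP series.

    ARV = (1/(N-1)) * sum_{k=1}^{N-1} |x_{k+1} - x_k|, the mean absolute
    change between consecutive valid readings. Unlike the SD it is sensitive
    to the order of the measures, so it captures short-term variability
    rather than overall dispersion around the mean.
    """
    vals = _as_values(series)
    if vals.size < 2:
        raise ValueError("variability undefined for fewer than two valid measures")
    return float(np.mean(np.abs(np.diff(vals))))


def sd_variability(series: BPSeries | Sequence[float]) -> float:
    """Sample standard deviation (divisor N-1) — the order-invariant baseline."""
    vals = _as_values(series)
    if vals.size < 2:
        raise ValueError("variability undefined for fewer than two valid measures")
    return float(np.std(vals, ddof=1))


def recording_quality(recording: AmbulatoryRecording) -> float:
    """Fraction of scheduled readings that are valid, in [0, 1]."""
    if recording.n_scheduled == 0:
        raise ValueError("recording has no scheduled readings")
    return recording.n_valid / recording.n_scheduled


def passes_quality(
    recording: AmbulatoryRecording, threshold: float = QUALITY_THRESHOLD
) -> bool:
    """True iff the valid fraction strictly exceeds ``threshold``."""
    return recording_quality(recording) > threshold


# ---------------------------------------------------------------------------
# delimited-text I/O


def recordings_to_frame(recordings: Iterable[AmbulatoryRecording]) -> pd.DataFrame:
    rows = [
        (rec.subject_id, r.timestamp, r.sbp, r.dbp, int(r.valid))
        for rec in recordings
        for r in rec.readings
    ]
    return pd.DataFrame(
        rows, columns=["subject_id", "timestamp_min", "sbp", "dbp", "valid"]
    )


def write_recordings(
    recordings: Iterable[AmbulatoryRecording], path, seed: int | None = None
) -> None:
    """Write recordings as CSV; the generating seed goes in a header comment."""
    frame = recordings_to_frame(recordings)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, index=False)


def read_recordings(path, schedule: Schedule | None = None) -> list[AmbulatoryRecording]:
    frame = pd.read_csv(path, comment="#")
    required = {"subject_id", "timestamp_min", "sbp", "dbp", "valid"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"recordings file missing columns: {sorted(missing)}")
    out = []
    for sid, grp in frame.groupby("subject_id", sort=False):
        readings = [
            BPReading(row.timestamp_min, row.sbp, row.dbp, bool(row.valid))
            for row in grp.sort_values("timestamp_min").itertuples()
        ]
        out.append(
            AmbulatoryRecording(str(sid), readings, schedule or Schedule())
        )
    return out
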