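"""Data model and CSV readers/writers for epoch actigraphy, sleep logs, and outcomes.

All files are plain comma-separated text with a header row and ISO-8601
timestamps in local wall-clock time.  Three record kinds are handled:

* epoch files — one row per 30-s epoch: ``timestamp, activity, off_wrist``
* sleep logs — one row per participant-morning: ``participant_id, log_date,
  bed_time, rise_time, quality, restfulness``
* outcome tables — one row per participant: ``participant_id, ptsd_dx,
  pcl5_total, nonptsd_dx, age``

Epoch series are materialized gap-free: a missing epoch is inserted with
``count = 0`` and ``off_wrist = True`` so that downstream day windows stay
rectangular.  Gap-filling never changes the sum of observed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "SleepLogEntry",
    "ParticipantOutcome",
    "EpochValidationError",
    "read_epoch_csv",
    "write_epoch_csv",
    "read_sleep_logs",
    "write_sleep_logs",
    "read_outcomes",
    "write_outcomes",
    "write_day_features",
    "read_day_features",
    "DAY_FEATURE_COLUMNS",
]


class EpochValidationError(ValueError):
    """Raised when an input file violates the record contracts."""


@dataclass
class EpochSeries:
    """A participant's uniformly spaced 30-s activity-count series.

    Parameters
    ----------
    participant_id : str
        Opaque identifier.
    start_time : datetime
        Local wall-clock timestamp of the first epoch.
    counts : np.ndarray
        Nonnegative activity counts, one per epoch.
    off_wrist : np.ndarray
        Boolean flags parallel to ``counts``; True marks epochs where the
        device was not worn (including materialized gaps).
    epoch_length : int
        Epoch duration in seconds (default 30).
    timezone_events : list of (datetime, int)
        Wall-clock offset changes (timestamp, offset delta in minutes), used
        by QC to taint days around a daylight-saving transition.
    """

    participant_id: str
    start_time: datetime
    counts: np.ndarray
    off_wrist: np.ndarray
    epoch_length: int = 30
    timezone_events: list[tuple[datetime, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.off_wrist = np.asarray(self.off_wrist, dtype=bool)
        if self.counts.ndim != 1 or len(self.counts) < 1:
            raise EpochValidationError("counts must be a nonempty 1-D sequence")
        if len(self.counts) != len(self.off_wrist):
            raise EpochValidationError("counts and off_wrist lengths differ")
        if not np.all(np.isfinite(self.counts)):
            raise EpochValidationError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise EpochValidationError("negative activity count")

    def __len__(self) -> int:
        return len(self.counts)

    def times(self) -> pd.DatetimeIndex:
        """Timestamps of every epoch."""
        return pd.date_range(
            self.start_time, periods=len(self), freq=pd.Timedelta(seconds=self.epoch_length)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochSeries):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.start_time == other.start_time
            and self.epoch_length == other.epoch_length
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.off_wrist, other.off_wrist)
        )


@dataclass(frozen=True)
class SleepLogEntry:
    """One morning's sleep log: the night's rest interval plus 1-10 ratings."""

    participant_id: str
    log_date: date
    bed_time: datetime
    rise_time: datetime
    quality: int
    restfulness: int

    def __post_init__(self) -> None:
        for name in ("quality", "restfulness"):
            v = getattr(self, name)
            if not (1 <= v <= 10):
                raise EpochValidationError(f"{name}={v} outside 1-10")
        if not self.bed_time < self.rise_time:
            raise EpochValidationError("bed_time must precede rise_time")
        if self.rise_time.date() != self.log_date:
            raise EpochValidationError("rise_time must fall on log_date (morning of waking)")


@dataclass(frozen=True)
class ParticipantOutcome:
    """Clinical outcome record for one participant.

    ``pcl31`` / ``pcl38`` are the probable-PTSD flags derived from the PCL-5
    total at the >=31 and >=38 cutoffs; ``pcl38`` implies ``pcl31``.
    """

    participant_id: str
    ptsd_dx: int | None
    pcl5_total: int
    nonptsd_dx: int
    age: float

    def __post_init__(self) -> None:
        if not (0 <= self.pcl5_total <= 80):
            raise EpochValidationError(f"pcl5_total={self.pcl5_total} outside 0-80")
        if self.ptsd_dx not in (0, 1, None):
            raise EpochValidationError("ptsd_dx must be 0, 1 or missing")
        if self.nonptsd_dx not in (0, 1):
            raise EpochValidationError("nonptsd_dx must be 0 or 1")

    @property
    def pcl31(self) -> int:
        return int(self.pcl5_total >= 31)

    @property
    def pcl38(self) -> int:
        return int(self.pcl5_total >= 38)


def read_epoch_csv(
    path: str | Path,
    epoch_length: int = 30,
    participant_id: str | None = None,
) -> EpochSeries:
    """Read one participant's epoch file into a gap-free :class:`EpochSeries`.

    Rows are sorted by timestamp; duplicated timestamps are rejected; missing
    epochs are inserted as off-wrist zeros.  An optional ``participant_id``
    column in the file must be single-valued.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - I/O failure message
        raise EpochValidationError(f"cannot read {path}: {exc}") from exc
    required = {"timestamp", "activity", "off_wrist"}
    missing = required - set(df.columns)
    if missing:
        raise EpochValidationError(f"{path}: missing columns {sorted(missing)}")
    if participant_id is None:
        if "participant_id" in df.columns:
            ids = df["participant_id"].unique()
            if len(ids) != 1:
                raise EpochValidationError(f"{path}: multiple participant ids {ids}")
            participant_id = str(ids[0])
        else:
            participant_id = path.stem

    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise EpochValidationError(
            f"{path}: malformed timestamp at row {row + 2}: {df['timestamp'].iloc[row]!r}"
        )
    order = np.argsort(ts.to_numpy(), kind="stable")
    ts = ts.iloc[order].reset_index(drop=True)
    counts = pd.to_numeric(df["activity"].iloc[order], errors="coerce").to_numpy(float)
    off = df["off_wrist"].iloc[order].astype(bool).to_numpy()
    if np.any(~np.isfinite(counts)):
        raise EpochValidationError(f"{path}: non-numeric activity value")
    if np.any(counts < 0):
        raise EpochValidationError(f"{path}: negative activity count")
    if ts.duplicated().any():
        dup = ts[ts.duplicated()].iloc[0]
        raise EpochValidationError(f"{path}: duplicate timestamp {dup}")

    step = timedelta(seconds=epoch_length)
    full_index = pd.date_range(ts.iloc[0], ts.iloc[-1], freq=step)
    offsets = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    if np.any(offsets % epoch_length != 0):
        bad = int(np.flatnonzero(offsets % epoch_length != 0)[0])
        raise EpochValidationError(
            f"{path}: timestamp {ts.iloc[bad]} not aligned to the {epoch_length}-s grid"
        )
    pos = (offsets // epoch_length).astype(int)
    full_counts = np.zeros(len(full_index))
    full_off = np.ones(len(full_index), dtype=bool)
    full_counts[pos] = counts
    full_off[pos] = off
    return EpochSeries(
        participant_id=participant_id,
        start_time=full_index[0].to_pydatetime(),
        counts=full_counts,
        off_wrist=full_off,
        epoch_length=epoch_length,
    )


def write_epoch_csv(series: EpochSeries, path: str | Path) -> None:
    """Write an :class:`EpochSeries` in the dialect :func:`read_epoch_csv` accepts."""
    df = pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "timestamp": series.times().strftime("%Y-%m-%dT%H:%M:%S"),
            "activity": series.counts,
            "off_wrist": series.off_wrist.astype(int),
        }
    )
    df.to_csv(path, index=False)


_LOG_COLUMNS = ["participant_id", "log_date", "bed_time", "rise_time", "quality", "restfulness"]


def read_sleep_logs(path: str | Path) -> list[SleepLogEntry]:
    """Read a sleep-log CSV; one entry per participant-date, ratings coerced to int."""
    df = pd.read_csv(path)
    missing = set(_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise EpochValidationError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(subset=["participant_id", "log_date"]).any():
        dup = df[df.duplicated(subset=["participant_id", "log_date"])].iloc[0]
        raise EpochValidationError(
            f"{path}: duplicate log for {dup['participant_id']} on {dup['log_date']}"
        )
    entries = []
    for _, row in df.iterrows():
        entries.append(
            SleepLogEntry(
                participant_id=str(row["participant_id"]),
                log_date=pd.Timestamp(row["log_date"]).date(),
                bed_time=pd.Timestamp(row["bed_time"]).to_pydatetime(),
                rise_time=pd.Timestamp(row["rise_time"]).to_pydatetime(),
                quality=int(row["quality"]),
                restfulness=int(row["restfulness"]),
            )
        )
    return entries


def write_sleep_logs(entries: Iterable[SleepLogEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "participant_id": e.participant_id,
                "log_date": e.log_date.isoformat(),
                "bed_time": e.bed_time.strftime("%Y-%m-%dT%H:%M:%S"),
                "rise_time": e.rise_time.strftime("%Y-%m-%dT%H:%M:%S"),
                "quality": e.quality,
                "restfulness": e.restfulness,
            }
            for e in entries
        ],
        columns=_LOG_COLUMNS,
    )
    df.to_csv(path, index=False)


_OUTCOME_COLUMNS = ["participant_id", "ptsd_dx", "pcl5_total", "nonptsd_dx", "age"]


def read_outcomes(path: str | Path) -> list[ParticipantOutcome]:
    df = pd.read_csv(path)
    missing = set(_OUTCOME_COLUMNS) - set(df.columns)
    if missing:
        raise EpochValidationError(f"{path}: missing columns {sorted(missing)}")
    if df["participant_id"].duplicated().any():
        raise EpochValidationError(f"{path}: duplicate participant_id")
    out = []
    for _, row in df.iterrows():
        dx = row["ptsd_dx"]
        out.append(
            ParticipantOutcome(
                participant_id=str(row["participant_id"]),
                ptsd_dx=None if pd.isna(dx) else int(dx),
                pcl5_total=int(row["pcl5_total"]),
                nonptsd_dx=int(row["nonptsd_dx"]),
                age=float(row["age"]),
            )
        )
    return out


def write_outcomes(outcomes: Iterable[ParticipantOutcome], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "participant_id": o.participant_id,
                "ptsd_dx": "" if o.ptsd_dx is None else o.ptsd_dx,
                "pcl5_total": o.pcl5_total,
                "nonptsd_dx": o.nonptsd_dx,
                "age": o.age,
            }
            for o in outcomes
        ],
        columns=_OUTCOME_COLUMNS,
    )
    df.to_csv(path, index=False)


#: Canonical column order of the day-level feature table: key columns first,
#: then the 16 objective features, then the 2 subjective ratings.
DAY_FEATURE_COLUMNS = [
    "participant_id",
    "day_index",
    "date",
    "mesor",
    "acrophase_time",
    "amplitude",
    "relative_amplitude",
    "mean_activity",
    "sd_activity",
    "rmssd_activity",
    "intradaily_variability",
    "interdaily_stability",
    "circadian_rhythm_strength",
    "m10",
    "l5",
    "total_sleep_time",
    "efficiency",
    "waso",
    "fragmentation",
    "quality",
    "restfulness",
]

#: The 18 model-feature columns (16 objective + 2 subjective).
FEATURE_NAMES = DAY_FEATURE_COLUMNS[3:]


def write_day_features(rows: pd.DataFrame, path: str | Path) -> None:
    """Write the day-level feature table as a flat CSV in canonical column order."""
    if len(rows) == 0:
        raise EpochValidationError("no day-feature rows to write")
    missing = set(DAY_FEATURE_COLUMNS) - set(rows.columns)
    if missing:
        raise EpochValidationError(f"day-feature table missing columns {sorted(missing)}")
    rows[DAY_FEATURE_COLUMNS].to_csv(path, index=False)


def read_day_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DAY_FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise EpochValidationError(f"{path}: missing columns {sorted(missing)}")
    df["participant_id"] = df["participant_id"].astype(str)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df[DAY_FEATURE_COLUMNS]
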