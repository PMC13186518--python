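"""Epoch-level sleep scoring and night-level sleep metrics.

Scoring follows the weighted-moving-window family of actigraphy algorithms:
each 30-s epoch inside the night's rest interval is scored *sleep* when the
weighted sum of activity counts over a symmetric window falls below a wake
threshold.  The default kernel spans +-2 min of 30-s epochs with weights
(0.04, 0.04, 0.2, 0.2, 2, 0.2, 0.2, 0.04, 0.04) and wake threshold 40
("medium"); both are configurable (low 20 / high 80).

From the scored sequence the night metrics are:

* sleep onset — start of the first run of >= 10 consecutive minutes of sleep;
* sleep offset — end of the last such run;
* TST — minutes scored sleep between onset and offset;
* WASO — minutes scored wake between onset and offset;
* efficiency — 100 x TST / rest-interval duration (bed-to-rise denominator);
* fragmentation — movement index (% of interval epochs with any activity)
  plus immobility-fragmentation index (% of immobile bouts lasting <= 1 min),
  the conventional sleep fragmentation index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np

from .epoch_io import EpochSeries

__all__ = [
    "RestInterval",
    "SleepNightMetrics",
    "ScoringConfig",
    "DEFAULT_KERNEL",
    "score_epochs",
    "night_metrics",
    "score_night",
]

#: Default scoring kernel: weights over (-4 .. +4) 30-s epochs, i.e. +-2 min.
DEFAULT_KERNEL = np.array([0.04, 0.04, 0.2, 0.2, 2.0, 0.2, 0.2, 0.04, 0.04])


@dataclass
class ScoringConfig:
    """Sleep-scoring parameters: kernel weights, wake threshold, onset rule."""

    kernel: np.ndarray = field(default_factory=lambda: DEFAULT_KERNEL.copy())
    threshold: float = 40.0  # "medium"; low=20, high=80
    onset_run_minutes: int = 10


@dataclass
class RestInterval:
    """One night's in-bed interval with its slice into the epoch series."""

    participant_id: str
    date: date  # calendar date of waking
    start: datetime  # bed time
    end: datetime  # rise time
    epoch_slice: slice

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("rest interval start must precede end")

    def duration_minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass
class SleepNightMetrics:
    """Sleep summary for one night; all durations in minutes."""

    total_sleep_time: float
    waso: float
    efficiency: float  # percent of the rest interval spent asleep
    fragmentation: float
    onset: datetime
    offset: datetime


def score_epochs(
    counts: np.ndarray,
    kernel: np.ndarray = DEFAULT_KERNEL,
    threshold: float = 40.0,
) -> np.ndarray:
    """Score each epoch sleep/wake from the weighted moving sum of counts.

    Returns a boolean array, True = sleep.  Edges are zero-padded so the
    window is always full.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or len(kernel) % 2 == 0:
        raise ValueError("kernel must be 1-D with odd length")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    counts = np.asarray(counts, dtype=float)
    half = len(kernel) // 2
    padded = np.pad(counts, half)
    # correlate (not convolve): kernel is symmetric by convention anyway
    weighted = np.correlate(padded, kernel, mode="valid")
    return weighted < threshold


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def night_metrics(
    interval: RestInterval,
    sleep: np.ndarray,
    counts: np.ndarray,
    epoch_length: int = 30,
    onset_run_minutes: int = 10,
) -> SleepNightMetrics | None:
    """Compute night metrics from a scored sleep sequence aligned to the interval.

    Returns ``None`` when no run of ``onset_run_minutes`` consecutive sleep
    epochs exists (metrics flagged missing for that night).
    """
    sleep = np.asarray(sleep, dtype=bool)
    counts = np.asarray(counts, dtype=float)
    if len(sleep) != len(counts):
        raise ValueError("sleep sequence and counts must be aligned")
    per_min = 60.0 / epoch_length
    min_run = int(round(onset_run_minutes * per_min))
    runs = [(a, b) for a, b in _runs(sleep) if (b - a) >= min_run]
    if not runs:
        return None
    onset_i = runs[0][0]
    offset_i = runs[-1][1]
    span = sleep[onset_i:offset_i]
    tst = float(np.sum(span)) / per_min
    waso = float(np.sum(~span)) / per_min
    duration = interval.duration_minutes()
    efficiency = 100.0 * tst / duration

    # Sleep fragmentation index over the whole rest interval.
    moving = counts > 0
    movement_index = 100.0 * float(np.mean(moving))
    immobile_bouts = _runs(~moving)
    if immobile_bouts:
        short = sum(1 for a, b in immobile_bouts if (b - a) <= per_min)
        immobility_frag = 100.0 * short / len(immobile_bouts)
    else:
        immobility_frag = 0.0

    step = timedelta(seconds=epoch_length)
    return SleepNightMetrics(
        total_sleep_time=tst,
        waso=waso,
        efficiency=efficiency,
        fragmentation=movement_index + immobility_frag,
        onset=interval.start + onset_i * step,
        offset=interval.start + offset_i * step,
    )


def score_night(
    series: EpochSeries,
    interval: RestInterval,
    config: ScoringConfig | None = None,
) -> SleepNightMetrics | None:
    """Score one rest interval of an epoch series and summarize it."""
    cfg = config or ScoringConfig()
    sl = interval.epoch_slice
    counts = series.counts[sl]
    if counts.size == 0:
        return None
    sleep = score_epochs(counts, cfg.kernel, cfg.threshold)
    return night_metrics(
        interval,
        sleep,
        counts,
        epoch_length=series.epoch_length,
        onset_run_minutes=cfg.onset_run_minutes,
    )
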