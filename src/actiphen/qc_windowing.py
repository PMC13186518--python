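"""Segment actigraphy recordings into analysis days and apply exclusion rules.

A recording is split into local midnight-to-midnight calendar days.  A day is
retained for feature extraction only if all of the following hold:

* it contains a full 24 h of epochs (2880 epochs at 30 s);
* off-wrist time is below 30% of the day;
* a sleep log exists for that waking date;
* it is not within 2 days after a daylight-saving transition;
* it is neither the first nor the last study day (circadian measures on those
  days would span less than a full window).

With a clean 7-day recording this retains days 2-6, i.e. 5 days per person.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

import numpy as np

from .epoch_io import EpochSeries, SleepLogEntry

__all__ = ["AnalysisDay", "QcConfig", "segment_days", "apply_exclusions"]


@dataclass
class QcConfig:
    """Day-exclusion thresholds.

    off_wrist_max : float
        Days with off-wrist fraction >= this value are excluded (default 0.30).
    dst_exclusion_days : int
        Number of days after a time change that are excluded, in addition to
        the transition day itself (default 2).
    drop_first_last : bool
        Unconditionally drop study days 1 and 7 (default True).
    """

    off_wrist_max: float = 0.30
    dst_exclusion_days: int = 2
    drop_first_last: bool = True


@dataclass
class AnalysisDay:
    """One participant calendar day with QC flags.

    ``epoch_slice`` indexes into the participant's :class:`EpochSeries` and
    covers local midnight to midnight of ``date``.
    """

    participant_id: str
    day_index: int
    date: date
    epoch_slice: slice
    off_wrist_fraction: float
    has_sleep_log: bool = False
    dst_tainted: bool = False
    full_24h: bool = False
    retained: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.off_wrist_fraction <= 1.0):
            raise ValueError("off_wrist_fraction outside [0, 1]")


def segment_days(series: EpochSeries) -> list[AnalysisDay]:
    """Split a gap-free epoch series into calendar days.

    Returns one :class:`AnalysisDay` per calendar date touched by the
    recording, in chronological order, with ``day_index`` starting at 1.
    ``full_24h`` is True only when the day holds exactly 24 h worth of epochs.
    """
    n = len(series)
    if n == 0:
        raise ValueError("empty epoch series")
    epd = int(round(86400 / series.epoch_length))  # epochs per full day
    start = series.start_time
    days: list[AnalysisDay] = []
    first_midnight = datetime.combine(start.date(), time())
    day_idx = 0
    d = first_midnight
    while True:
        lo_s = (d - start).total_seconds() / series.epoch_length
        hi_s = (d + timedelta(days=1) - start).total_seconds() / series.epoch_length
        lo = max(0, int(np.ceil(lo_s)))
        hi = min(n, int(np.ceil(hi_s)))
        if lo >= n:
            break
        day_idx += 1
        off = series.off_wrist[lo:hi]
        days.append(
            AnalysisDay(
                participant_id=series.participant_id,
                day_index=day_idx,
                date=d.date(),
                epoch_slice=slice(lo, hi),
                off_wrist_fraction=float(np.mean(off)) if hi > lo else 1.0,
                full_24h=(hi - lo) == epd,
            )
        )
        d += timedelta(days=1)
    return days


def apply_exclusions(
    days: list[AnalysisDay],
    sleep_logs: list[SleepLogEntry],
    dst_events: list[tuple[datetime, int]] | None = None,
    config: QcConfig | None = None,
) -> list[AnalysisDay]:
    """Set ``has_sleep_log``, ``dst_tainted`` and ``retained`` on each day.

    ``dst_events`` are (transition timestamp, offset change in minutes) pairs;
    the transition day and the ``dst_exclusion_days`` following days are
    tainted for that participant.  Returns the same day objects, flags set.
    """
    cfg = config or QcConfig()
    dst_events = dst_events or []
    log_dates = {(e.participant_id, e.log_date) for e in sleep_logs}
    if days:
        last_index = max(d.day_index for d in days)
    for day in days:
        day.has_sleep_log = (day.participant_id, day.date) in log_dates
        day.dst_tainted = any(
            0 <= (day.date - ev.date()).days <= cfg.dst_exclusion_days
            for ev, _delta in dst_events
        )
        edge = cfg.drop_first_last and day.day_index in (1, last_index)
        day.retained = (
            day.full_24h
            and day.off_wrist_fraction < cfg.off_wrist_max
            and day.has_sleep_log
            and not day.dst_tainted
            and not edge
        )
    return days
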