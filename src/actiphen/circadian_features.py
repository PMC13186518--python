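"""Cosinor and nonparametric rest-activity features per participant-day.

The single-component cosinor model is

    y(t) = M + A cos(2 pi (t - t_peak) / 24) + e

fitted by exact least squares via the linearization
y = M + b cos(w t) + g sin(w t), w = 2 pi / period, with A = sqrt(b^2 + g^2)
and acrophase time t_peak = atan2(g, b) / w mod period.

Nonparametric day metrics follow the standard rest-activity rhythm
literature: intradaily variability (IV) on hourly means within the day,
interdaily stability (IS) on hourly means across a participant's retained
days, M10/L5 as extremal consecutive-window means at epoch resolution, and
relative amplitude RA = (M10 - L5) / (M10 + L5).  Circadian rhythm strength
is the variance explained (R^2) by the day's 24-h cosinor fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epoch_io import DAY_FEATURE_COLUMNS, EpochSeries, SleepLogEntry
from .qc_windowing import AnalysisDay
from .sleep_metrics import SleepNightMetrics

__all__ = [
    "CosinorFit",
    "fit_cosinor",
    "nonparametric_day_features",
    "interdaily_stability",
    "circadian_rhythm_strength",
    "assemble_day_rows",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CosinorFit:
    """Least-squares cosinor parameters for one day of activity."""

    mesor: float
    amplitude: float
    acrophase_time: float  # hours in [0, period)
    r_squared: float


def fit_cosinor(times_h: np.ndarray, counts: np.ndarray, period: float = 24.0) -> CosinorFit:
    """Exact least-squares single-component cosinor fit.

    Parameters
    ----------
    times_h : array of sample times in hours.
    counts : activity counts at those times.
    period : rhythm period in hours (default 24).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(counts, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and counts must be 1-D and aligned")
    if len(np.unique(t)) < 3:
        raise ValueError("cosinor fit needs >= 3 distinct time points")
    if not np.all(np.isfinite(y)):
        raise ValueError("counts must be finite")
    w = 2.0 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta, gamma = coef
    amplitude = float(np.hypot(beta, gamma))
    acrophase = float(np.arctan2(gamma, beta) / w % period)
    resid = y - X @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sst == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / sst)
    return CosinorFit(float(mesor), amplitude, acrophase, r2)


def _hourly_means(times_h: np.ndarray, counts: np.ndarray, bin_minutes: int = 60) -> np.ndarray:
    """Mean count per within-day time bin; NaN where a bin has no data."""
    nbins = int(round(24 * 60 / bin_minutes))
    t = np.asarray(times_h, dtype=float)
    x = np.asarray(counts, dtype=float)
    keep = np.isfinite(x)
    t, x = t[keep], x[keep]
    idx = np.floor((t % 24.0) * 60.0 / bin_minutes).astype(int)
    idx = np.clip(idx, 0, nbins - 1)
    sums = np.bincount(idx, weights=x, minlength=nbins)
    ns = np.bincount(idx, minlength=nbins)
    with np.errstate(invalid="ignore"):
        return np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)


def intradaily_variability(values: np.ndarray) -> float:
    """IV = n * sum of squared successive differences / ((n-1) * total variance).

    Computed on hourly (or otherwise binned) means of a single day; ~0 for a
    smooth sinusoid, ~2 in expectation for white noise.  NaN when the input
    is constant (undefined).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        return float("nan")
    denom = (n - 1) * np.sum((x - x.mean()) ** 2)
    if denom == 0:
        return float("nan")
    return float(n * np.sum(np.diff(x) ** 2) / denom)


def _window_extrema(counts: np.ndarray, epochs_per_hour: int) -> tuple[float, float]:
    """(M10, L5): extremal means over consecutive 10-h / 5-h windows.

    Windows slide at epoch resolution and do not wrap across midnight.
    NaN-valued epochs (off-wrist) are excluded from window means.
    """
    x = np.asarray(counts, dtype=float)
    valid = np.isfinite(x)
    filled = np.where(valid, x, 0.0)

    def window_means(width: int) -> np.ndarray:
        if len(x) < width:
            return np.array([np.nanmean(x)])
        csum = np.concatenate([[0.0], np.cumsum(filled)])
        cn = np.concatenate([[0], np.cumsum(valid.astype(int))])
        sums = csum[width:] - csum[:-width]
        ns = cn[width:] - cn[:-width]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)

    m10 = float(np.nanmax(window_means(10 * epochs_per_hour)))
    l5 = float(np.nanmin(window_means(5 * epochs_per_hour)))
    return m10, l5


def nonparametric_day_features(
    times_h: np.ndarray,
    counts: np.ndarray,
    epoch_length: int = 30,
    hourly_bin_minutes: int = 60,
) -> dict[str, float]:
    """Nonparametric activity features for one full day.

    ``counts`` may contain NaN for off-wrist epochs; those are excluded from
    every statistic rather than treated as zero activity.
    """
    x = np.asarray(counts, dtype=float)
    obs = x[np.isfinite(x)]
    if obs.size == 0:
        raise ValueError("day has no observed epochs")
    mean_activity = float(np.mean(obs))
    sd_activity = float(np.std(obs, ddof=1)) if obs.size > 1 else 0.0
    diffs = np.diff(obs)
    rmssd = float(np.sqrt(np.mean(diffs**2))) if diffs.size else 0.0
    iv = intradaily_variability(_hourly_means(times_h, x, hourly_bin_minutes))
    epochs_per_hour = int(round(3600 / epoch_length))
    m10, l5 = _window_extrema(x, epochs_per_hour)
    ra = (m10 - l5) / (m10 + l5) if (m10 + l5) > 0 else float("nan")
    return {
        "mean_activity": mean_activity,
        "sd_activity": sd_activity,
        "rmssd_activity": rmssd,
        "intradaily_variability": iv,
        "m10": m10,
        "l5": l5,
        "relative_amplitude": ra,
    }


def interdaily_stability(day_profiles: list[np.ndarray]) -> float:
    """IS across a participant's retained days, on hourly means.

    IS = (n * sum_h (xbar_h - xbar)^2) / (p * sum_i (x_i - xbar)^2) where
    x_i are all hourly values pooled over days, xbar_h the mean of hour h
    across days, and p the number of hourly bins.  Requires >= 2 days;
    returns NaN otherwise, and 1.0 when days repeat identically.
    """
    profiles = [np.asarray(p, dtype=float) for p in day_profiles]
    if len(profiles) < 2:
        return float("nan")
    mat = np.vstack(profiles)  # days x hours
    if np.isnan(mat).any():
        col_means = np.nanmean(mat, axis=0)
        inds = np.where(np.isnan(mat))
        mat[inds] = np.take(col_means, inds[1])
    n = mat.size
    grand = mat.mean()
    hourly = mat.mean(axis=0)
    denom = hourly.shape[0] * np.sum((mat - grand) ** 2)
    if denom == 0:
        return float("nan")
    return float(n * np.sum((hourly - grand) ** 2) / denom)


def circadian_rhythm_strength(times_h: np.ndarray, counts: np.ndarray) -> float:
    """Variance explained (R^2) by the day's 24-h cosinor fit."""
    return fit_cosinor(times_h, counts, period=24.0).r_squared


def _day_arrays(series: EpochSeries, day: AnalysisDay) -> tuple[np.ndarray, np.ndarray]:
    """(hours-into-day, counts with NaN at off-wrist epochs) for one day."""
    sl = day.epoch_slice
    counts = series.counts[sl].astype(float).copy()
    counts[series.off_wrist[sl]] = np.nan
    n = sl.stop - sl.start
    first = series.start_time + pd.Timedelta(seconds=sl.start * series.epoch_length)
    h0 = first.hour + first.minute / 60 + first.second / 3600
    hours = h0 + np.arange(n) * (series.epoch_length / 3600.0)
    return hours, counts


def compute_participant_features(
    series: EpochSeries,
    retained_days: list[AnalysisDay],
    hourly_bin_minutes: int = 60,
) -> dict:
    """Per-day objective features plus the participant-level IS broadcast.

    Returns ``{"days": {date: feature dict}, "interdaily_stability": float}``.
    """
    per_day: dict = {}
    profiles = []
    for day in retained_days:
        hours, counts = _day_arrays(series, day)
        mask = np.isfinite(counts)
        fit = fit_cosinor(hours[mask], counts[mask])
        feats = nonparametric_day_features(
            hours, counts, series.epoch_length, hourly_bin_minutes
        )
        feats.update(
            mesor=fit.mesor,
            amplitude=fit.amplitude,
            acrophase_time=fit.acrophase_time,
            circadian_rhythm_strength=fit.r_squared,
        )
        per_day[day.date] = feats
        profiles.append(_hourly_means(hours, counts, hourly_bin_minutes))
    return {
        "days": per_day,
        "interdaily_stability": interdaily_stability(profiles),
    }


def assemble_day_rows(
    day_features: dict[tuple[str, object], dict],
    sleep_metrics: dict[tuple[str, object], SleepNightMetrics | None],
    logs: list[SleepLogEntry],
    day_index: dict[tuple[str, object], int],
    is_by_participant: dict[str, float],
) -> pd.DataFrame:
    """Join objective features, night metrics and log ratings into day rows.

    Inputs are keyed by (participant_id, date).  Rows missing any required
    feature (e.g. a night with no scorable sleep) are dropped with a logged
    reason.  Raises on duplicate keys.
    """
    log_map: dict[tuple[str, object], SleepLogEntry] = {}
    for e in logs:
        key = (e.participant_id, e.log_date)
        if key in log_map:
            raise ValueError(f"duplicate sleep log for {key}")
        log_map[key] = e

    rows = []
    for key in sorted(day_features, key=lambda k: (k[0], str(k[1]))):
        pid, d = key
        feats = day_features[key]
        night = sleep_metrics.get(key)
        log = log_map.get(key)
        if night is None:
            logger.info("dropping %s %s: no scorable sleep", pid, d)
            continue
        if log is None:
            logger.info("dropping %s %s: missing sleep log", pid, d)
            continue
        row = {
            "participant_id": pid,
            "day_index": day_index.get(key, -1),
            "date": d,
            **feats,
            "interdaily_stability": is_by_participant.get(pid, float("nan")),
            "total_sleep_time": night.total_sleep_time,
            "efficiency": night.efficiency,
            "waso": night.waso,
            "fragmentation": night.fragmentation,
            "quality": log.quality,
            "restfulness": log.restfulness,
        }
        if any(
            isinstance(v, float) and not np.isfinite(v)
            for k, v in row.items()
            if k not in ("participant_id", "date")
        ):
            bad = [k for k, v in row.items()
                   if isinstance(v, float) and not np.isfinite(v)]
            logger.info("dropping %s %s: non-finite features %s", pid, d, bad)
            continue
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=DAY_FEATURE_COLUMNS)
    return pd.DataFrame(rows)[DAY_FEATURE_COLUMNS]
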