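"""Synthetic study-cohort generator: epoch actigraphy, sleep logs, outcomes.

Emulates a one-week wrist-actigraphy protocol in a cohort of ~33 male
veterans: per participant-day, activity follows a 24-h cosinor
(mesor + amplitude x cos(2 pi (t - t_peak)/24)) with AR(1) epoch noise,
clipped at zero, with activity suppressed inside each night's in-bed
interval except for planted sleep-onset latency, discrete wake bouts, and
isolated movement epochs.  Diagnosed participants receive signed effect
shifts: lower subjective restfulness, longer wake after sleep onset, lower
sleep efficiency (via longer onset latency), more sleep fragmentation, and
a later acrophase.  Subjective quality and restfulness are drawn jointly
with a configurable correlation (default 0.9), at both the person and the
night level.  PCL-5 totals are drawn so the >=31 and >=38 probable-PTSD
flags land near realistic prevalences (roughly 10/33 and 7/33 in
expectation).

Everything is deterministic given the seed, and the emitted CSV files are
readable by :mod:`actiphen.epoch_io` without modification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .epoch_io import (
    EpochSeries,
    ParticipantOutcome,
    SleepLogEntry,
    write_epoch_csv,
    write_outcomes,
    write_sleep_logs,
)

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "planted_truth"]

_START_DATE = date(2024, 6, 3)  # arbitrary Monday, clear of DST transitions


@dataclass
class CohortConfig:
    """Generative parameters for the synthetic cohort.

    Effect sizes are signed shifts applied to diagnosed participants;
    defaults follow the directions reported for PTSD in the actigraphy
    literature (diagnosed: less restful, more WASO, less efficient, more
    fragmented, later acrophase).
    """

    n_participants: int = 33
    n_days: int = 7
    epoch_length: int = 30
    prevalence_dx: float = 8 / 33
    prevalence_nonptsd: float = 0.45

    # circadian activity process
    mesor_mean: float = 150.0
    mesor_sd: float = 20.0
    amplitude_mean: float = 120.0
    amplitude_sd: float = 15.0
    t_peak_hours: float = 15.0
    t_peak_sd: float = 1.0
    ar1_coef: float = 0.6
    noise_sd: float = 60.0
    hour_noise_sd: float = 0.35  # multiplicative hour-scale waking modulation

    # sleep process (minutes unless noted); *_person_sd are stable
    # between-person traits, the remaining noise is night-to-night
    bed_hour: float = 23.0
    rise_hour: float = 7.0
    bed_rise_sd_hours: float = 0.4
    onset_latency_minutes: float = 8.0
    latency_person_sd: float = 8.0
    waso_base_minutes: float = 20.0
    waso_person_sd: float = 10.0
    waso_night_sd: float = 6.0
    n_wake_bouts: int = 3
    wake_bout_count: float = 300.0
    movement_epoch_prob: float = 0.05  # isolated low-count movement during sleep
    movement_prob_person_sd: float = 0.03
    movement_epoch_count: float = 12.0

    # subjective ratings (1-10)
    restfulness_mean: float = 7.0
    quality_mean: float = 7.0
    rating_person_sd: float = 0.8
    rating_night_sd: float = 1.2
    rho_quality_restfulness: float = 0.9

    # PCL-5 totals (0-80)
    pcl_control_mean: float = 20.0
    pcl_dx_mean: float = 44.0
    pcl_sd: float = 9.0

    # signed diagnosed-group effects, each roughly one between-person SD so
    # group differences are moderate (study-like), not perfectly separating
    delta_restfulness: float = -1.0
    delta_waso_minutes: float = 12.0
    delta_efficiency: float = -1.5  # percentage points, via onset latency
    delta_fragmentation: float = 4.0  # index points, via movement epochs
    delta_acrophase_hours: float = 0.75

    age_mean: float = 41.0
    age_sd: float = 5.3
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        if self.n_participants < 4:
            raise ValueError("need n_participants >= 4")
        for name in ("prevalence_dx", "prevalence_nonptsd"):
            p = getattr(self, name)
            if not (0 < p < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        interval_min = ((24 - self.bed_hour) + self.rise_hour) * 60
        latency = self.onset_latency_minutes + self._latency_shift()
        wake = self.waso_base_minutes + self.delta_waso_minutes
        if latency < 0 or latency + wake >= interval_min:
            raise ValueError(
                "infeasible effect configuration: planted wake exceeds the "
                "rest interval or implies efficiency below 0"
            )
        if self.restfulness_mean + self.delta_restfulness < 1:
            raise ValueError("delta_restfulness pushes ratings below the 1-10 scale")

    def _latency_shift(self) -> float:
        """Extra onset latency (minutes) realizing the efficiency shift."""
        interval_min = ((24 - self.bed_hour) + self.rise_hour) * 60
        return -self.delta_efficiency / 100.0 * interval_min


@dataclass
class SyntheticCohort:
    """In-memory generated cohort plus the planted generative truth."""

    config: CohortConfig
    series: dict[str, EpochSeries]
    sleep_logs: list[SleepLogEntry]
    outcomes: list[ParticipantOutcome]
    truth: dict

    def to_csv(self, out_dir: str | Path) -> None:
        """Write epoch files (one per participant), sleep logs and outcomes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pid, s in self.series.items():
            write_epoch_csv(s, out / f"epochs_{pid}.csv")
        write_sleep_logs(self.sleep_logs, out / "sleep_logs.csv")
        write_outcomes(self.outcomes, out / "outcomes.csv")


def planted_truth(config: CohortConfig) -> dict:
    """Exact per-group generative parameters, for parameter-recovery tests.

    Features the pipeline estimates but that are not directly planted are
    marked ``"emergent"``.
    """
    interval_min = ((24 - config.bed_hour) + config.rise_hour) * 60
    lat0 = config.onset_latency_minutes
    lat1 = lat0 + config._latency_shift()

    def eff(latency: float, waso: float) -> float:
        return 100.0 * (interval_min - latency - waso) / interval_min

    return {
        "control": {
            "t_peak_hours": config.t_peak_hours,
            "mesor": config.mesor_mean,
            "amplitude": config.amplitude_mean,
            "restfulness": config.restfulness_mean,
            "quality": config.quality_mean,
            "waso_minutes": config.waso_base_minutes,
            "efficiency_percent": eff(lat0, config.waso_base_minutes),
            "movement_epoch_prob": config.movement_epoch_prob,
            "pcl5_mean": config.pcl_control_mean,
        },
        "diagnosed": {
            "t_peak_hours": config.t_peak_hours + config.delta_acrophase_hours,
            "mesor": config.mesor_mean,
            "amplitude": config.amplitude_mean,
            "restfulness": config.restfulness_mean + config.delta_restfulness,
            "quality": config.quality_mean + config.rho_quality_restfulness
            * config.delta_restfulness,
            "waso_minutes": config.waso_base_minutes + config.delta_waso_minutes,
            "efficiency_percent": eff(
                lat1, config.waso_base_minutes + config.delta_waso_minutes
            ),
            "movement_epoch_prob": config.movement_epoch_prob
            + config.delta_fragmentation / 100.0,
            "pcl5_mean": config.pcl_dx_mean,
        },
        "emergent": [
            "mean_activity", "sd_activity", "rmssd_activity",
            "intradaily_variability", "interdaily_stability",
            "circadian_rhythm_strength", "m10", "l5", "relative_amplitude",
            "total_sleep_time", "fragmentation",
        ],
        "rho_quality_restfulness": config.rho_quality_restfulness,
    }


def _draw_rating_pair(
    rng: np.random.Generator, rho: float, sd: float, size: int
) -> np.ndarray:
    """size x 2 draws from a bivariate normal with correlation rho."""
    cov = sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    return rng.multivariate_normal([0.0, 0.0], cov, size=size)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort deterministically from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    epd = int(round(86400 / config.epoch_length))
    n_epochs = config.n_days * epd
    step_h = config.epoch_length / 3600.0

    n_pos = int(round(config.prevalence_dx * n))
    dx = np.zeros(n, dtype=int)
    dx[rng.permutation(n)[:n_pos]] = 1

    series: dict[str, EpochSeries] = {}
    logs: list[SleepLogEntry] = []
    outcomes: list[ParticipantOutcome] = []
    start_dt = datetime.combine(_START_DATE, time())
    latency_shift = config._latency_shift()

    for i in range(n):
        pid = f"P{i + 1:03d}"
        is_dx = bool(dx[i])
        mesor = rng.normal(config.mesor_mean, config.mesor_sd)
        amplitude = max(10.0, rng.normal(config.amplitude_mean, config.amplitude_sd))
        t_peak = rng.normal(
            config.t_peak_hours + config.delta_acrophase_hours * is_dx,
            config.t_peak_sd,
        )

        hours = (np.arange(n_epochs) * step_h) % 24.0
        signal = mesor + amplitude * np.cos(2 * np.pi * (hours - t_peak) / 24.0)
        # slow hour-scale modulation of waking activity (weather, schedule,
        # behavior) so day profiles do not repeat unrealistically well
        eph = int(round(3600 / config.epoch_length))
        n_hours = n_epochs // eph
        hour_factor = np.repeat(
            np.clip(rng.normal(1.0, config.hour_noise_sd, size=n_hours), 0.0, None),
            eph,
        )[:n_epochs]
        signal = signal * hour_factor
        # AR(1) epoch noise, stationary-variance normalized
        a = config.ar1_coef
        eps = rng.normal(0.0, config.noise_sd, size=n_epochs)
        innov = np.sqrt(1 - a**2) * eps
        innov[0] = eps[0]
        noise = lfilter([1.0], [1.0, -a], innov)
        counts = np.clip(signal + noise, 0.0, None)

        u_q, u_r = _draw_rating_pair(
            rng, config.rho_quality_restfulness, config.rating_person_sd, 1
        )[0]
        # stable sleep traits
        latency_trait = rng.normal(0.0, config.latency_person_sd)
        waso_trait = rng.normal(0.0, config.waso_person_sd)
        move_prob = float(np.clip(
            rng.normal(
                config.movement_epoch_prob
                + (config.delta_fragmentation / 100.0) * is_dx,
                config.movement_prob_person_sd,
            ),
            0.005, 0.5,
        ))

        # nights: waking dates day 2 .. n_days
        for d in range(1, config.n_days):
            wake_date = _START_DATE + timedelta(days=d)
            bed = datetime.combine(
                wake_date - timedelta(days=1), time()
            ) + timedelta(hours=config.bed_hour + rng.normal(0, config.bed_rise_sd_hours))
            rise = datetime.combine(wake_date, time()) + timedelta(
                hours=config.rise_hour + rng.normal(0, config.bed_rise_sd_hours)
            )
            lo = int(np.ceil((bed - start_dt).total_seconds() / config.epoch_length))
            hi = int(np.ceil((rise - start_dt).total_seconds() / config.epoch_length))
            lo, hi = max(lo, 0), min(hi, n_epochs)
            n_night = hi - lo

            night = np.zeros(n_night)
            move = rng.random(n_night) < move_prob
            night[move] = rng.uniform(2.0, config.movement_epoch_count, size=move.sum())

            per_ep = 60.0 / config.epoch_length
            latency_ep = int(round(
                max(0.0, config.onset_latency_minutes + latency_trait
                    + latency_shift * is_dx + rng.normal(0, 2.0)) * per_ep
            ))
            latency_ep = min(latency_ep, max(n_night - 1, 0))
            night[:latency_ep] = rng.uniform(
                0.5 * config.wake_bout_count, config.wake_bout_count, size=latency_ep
            )

            waso_min = max(
                2.0,
                config.waso_base_minutes
                + waso_trait
                + config.delta_waso_minutes * is_dx
                + rng.normal(0, config.waso_night_sd),
            )
            waso_ep = int(round(waso_min * per_ep))
            n_bouts = max(1, config.n_wake_bouts + int(rng.integers(-1, 2)))
            cuts = np.sort(rng.integers(1, waso_ep, size=n_bouts - 1)) if n_bouts > 1 else []
            bout_lens = np.diff(np.concatenate([[0], cuts, [waso_ep]])).astype(int)
            # place bouts in disjoint blocks of the mid-night region so the
            # planted total is not eroded by overlap
            margin = 25 * int(per_ep)
            usable_lo = latency_ep + margin
            usable_hi = n_night - margin
            if usable_hi > usable_lo:
                block = (usable_hi - usable_lo) // len(bout_lens)
                for b, length in enumerate(bout_lens):
                    length = max(int(length), 1)
                    b_lo = usable_lo + b * block
                    b_hi = min(b_lo + block, usable_hi) - length - 2
                    if b_hi <= b_lo:
                        b_hi = b_lo + 1
                    s = int(rng.integers(b_lo, b_hi))
                    e = min(s + length, n_night)
                    night[s:e] = rng.uniform(
                        0.7 * config.wake_bout_count,
                        1.3 * config.wake_bout_count,
                        size=e - s,
                    )
            counts[lo:hi] = night

            e_q, e_r = _draw_rating_pair(
                rng, config.rho_quality_restfulness, config.rating_night_sd, 1
            )[0]
            rest = config.restfulness_mean + config.delta_restfulness * is_dx + u_r + e_r
            qual = (
                config.quality_mean
                + config.rho_quality_restfulness * config.delta_restfulness * is_dx
                + u_q + e_q
            )
            logs.append(
                SleepLogEntry(
                    participant_id=pid,
                    log_date=wake_date,
                    bed_time=bed.replace(microsecond=0),
                    rise_time=rise.replace(microsecond=0),
                    quality=int(np.clip(round(qual), 1, 10)),
                    restfulness=int(np.clip(round(rest), 1, 10)),
                )
            )

        series[pid] = EpochSeries(
            participant_id=pid,
            start_time=start_dt,
            counts=np.round(counts, 1),
            off_wrist=np.zeros(n_epochs, dtype=bool),
            epoch_length=config.epoch_length,
        )

        pcl = int(np.clip(round(rng.normal(
            config.pcl_dx_mean if is_dx else config.pcl_control_mean, config.pcl_sd
        )), 0, 80))
        outcomes.append(
            ParticipantOutcome(
                participant_id=pid,
                ptsd_dx=int(is_dx),
                pcl5_total=pcl,
                nonptsd_dx=int(rng.random() < config.prevalence_nonptsd),
                age=float(np.round(rng.normal(config.age_mean, config.age_sd), 1)),
            )
        )

    return SyntheticCohort(
        config=config,
        series=series,
        sleep_logs=logs,
        outcomes=outcomes,
        truth=planted_truth(config),
    )
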