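"""End-to-end orchestration: epochs + logs + outcomes -> evaluated models.

``build_day_features`` runs QC windowing, sleep scoring and feature
extraction to produce the day-level feature table; ``run_outcome`` then
performs feature selection, LOSO gradient-boosted classification,
person-level evaluation, attributions and the discriminant-validity
regressions for one outcome definition (clinician diagnosis, PCL-5>=31 or
PCL-5>=38).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circadian_features import assemble_day_rows, compute_participant_features
from .epoch_io import FEATURE_NAMES, EpochSeries, ParticipantOutcome, SleepLogEntry
from .evaluation import (
    ModelRunResult,
    attribution_summary,
    confusion_metrics,
    roc_auc,
)
from .feature_selection import SelectionReport, aggregate_person, select_top_k
from .loso_model import LosoConfig, check_no_leakage, loso_cv, person_scores
from .qc_windowing import QcConfig, apply_exclusions, segment_days
from .sleep_metrics import RestInterval, ScoringConfig, score_night
from .validity_regression import LogisticResult, OlsResult, fit_discriminant_ols, fit_logistic

__all__ = ["PipelineConfig", "build_day_features", "run_outcome", "OutcomeRun",
           "outcome_labels", "OUTCOMES"]

OUTCOMES = ("dx", "pcl31", "pcl38")


@dataclass
class PipelineConfig:
    qc: QcConfig = field(default_factory=QcConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    loso: LosoConfig = field(default_factory=LosoConfig)
    hourly_bin_minutes: int = 60
    n_selected: int = 3
    r_max: float = 0.70
    threshold: float = 0.5
    selection_scope: str = "full_sample"  # or "within_fold"


def build_day_features(
    series_by_participant: dict[str, EpochSeries],
    sleep_logs: list[SleepLogEntry],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """QC-filter each recording and compute the day-level feature table."""
    cfg = config or PipelineConfig()
    logs_by_pid: dict[str, list[SleepLogEntry]] = {}
    for e in sleep_logs:
        logs_by_pid.setdefault(e.participant_id, []).append(e)

    all_features: dict = {}
    all_nights: dict = {}
    day_index: dict = {}
    is_by_participant: dict[str, float] = {}
    for pid, series in series_by_participant.items():
        days = segment_days(series)
        days = apply_exclusions(
            days, logs_by_pid.get(pid, []), series.timezone_events, cfg.qc
        )
        retained = [d for d in days if d.retained]
        if not retained:
            continue
        feats = compute_participant_features(series, retained, cfg.hourly_bin_minutes)
        is_by_participant[pid] = feats["interdaily_stability"]
        log_map = {e.log_date: e for e in logs_by_pid.get(pid, [])}
        for day in retained:
            key = (pid, day.date)
            all_features[key] = feats["days"][day.date]
            day_index[key] = day.day_index
            log = log_map.get(day.date)
            if log is None:
                continue
            lo = int(
                np.ceil(
                    (log.bed_time - series.start_time).total_seconds()
                    / series.epoch_length
                )
            )
            hi = int(
                np.ceil(
                    (log.rise_time - series.start_time).total_seconds()
                    / series.epoch_length
                )
            )
            lo, hi = max(lo, 0), min(hi, len(series))
            interval = RestInterval(
                participant_id=pid,
                date=day.date,
                start=log.bed_time,
                end=log.rise_time,
                epoch_slice=slice(lo, hi),
            )
            all_nights[key] = score_night(series, interval, cfg.scoring)

    return assemble_day_rows(
        all_features, all_nights, sleep_logs, day_index, is_by_participant
    )


def outcome_labels(
    outcomes: list[ParticipantOutcome], outcome_name: str
) -> dict[str, int]:
    """Binary labels per participant for one outcome definition.

    Participants with a missing clinician diagnosis are omitted from the
    ``dx`` labels (per-outcome subsets).
    """
    if outcome_name == "dx":
        return {
            o.participant_id: int(o.ptsd_dx)
            for o in outcomes
            if o.ptsd_dx is not None
        }
    if outcome_name == "pcl31":
        return {o.participant_id: o.pcl31 for o in outcomes}
    if outcome_name == "pcl38":
        return {o.participant_id: o.pcl38 for o in outcomes}
    raise ValueError(f"unknown outcome {outcome_name!r}")


@dataclass
class OutcomeRun:
    """Everything produced for one outcome definition."""

    result: ModelRunResult
    selection: SelectionReport
    ols: OlsResult
    logistic: LogisticResult
    folds: list


def run_outcome(
    day_rows: pd.DataFrame,
    outcomes: list[ParticipantOutcome],
    outcome_name: str,
    seed: int,
    config: PipelineConfig | None = None,
) -> OutcomeRun:
    """Feature selection + LOSO model + evaluation + validity regressions."""
    cfg = config or PipelineConfig()
    labels = outcome_labels(outcomes, outcome_name)
    rows = day_rows[day_rows["participant_id"].isin(labels)]

    person = aggregate_person(rows, list(FEATURE_NAMES))
    y_person = person["participant_id"].map(labels).to_numpy(dtype=int)
    selection = select_top_k(
        person,
        y_person,
        list(FEATURE_NAMES),
        outcome_name=outcome_name,
        k=cfg.n_selected,
        r_max=cfg.r_max,
    )

    if cfg.selection_scope == "within_fold":
        # honest variant: re-select features on each fold's training persons
        features_by_fold: dict[str, list[str]] = {}
        for pid in sorted(rows["participant_id"].unique()):
            tr_person = person[person["participant_id"] != pid]
            y_tr = tr_person["participant_id"].map(labels).to_numpy(dtype=int)
            rep = select_top_k(
                tr_person, y_tr, list(FEATURE_NAMES),
                outcome_name=outcome_name, k=cfg.n_selected, r_max=cfg.r_max,
            )
            features_by_fold[pid] = rep.accepted
        selected: list[str] | dict[str, list[str]] = features_by_fold
    else:
        selected = selection.accepted
    folds = loso_cv(rows, labels, selected, seed=seed, config=cfg.loso)
    check_no_leakage(folds, rows, labels)
    scores = person_scores(folds)
    pids = sorted(scores)
    s = np.array([scores[p] for p in pids])
    y = np.array([labels[p] for p in pids])

    auc, lo, hi = roc_auc(s, y, seed=seed)
    cm = confusion_metrics(s, y, threshold=cfg.threshold)

    mean_shap, mean_gain = attribution_summary(folds)

    result = ModelRunResult(
        outcome_name=outcome_name,
        person_scores=scores,
        labels={p: int(labels[p]) for p in pids},
        auc=auc,
        auc_ci=(lo, hi),
        accuracy=cm["accuracy"],
        sensitivity=cm["sensitivity"],
        specificity=cm["specificity"],
        precision=cm["precision"],
        f1=cm["f1"],
        mean_abs_shap=mean_shap,
        mean_gain=mean_gain,
        selected_features=selection.accepted,
    )

    out_by_pid = {o.participant_id: o for o in outcomes}
    ols = fit_discriminant_ols(
        s,
        y,
        np.array([out_by_pid[p].nonptsd_dx for p in pids]),
        np.array([out_by_pid[p].age for p in pids]),
        term_names=(outcome_name, "nonptsd_dx", "age"),
    )
    logistic = fit_logistic(y, person.set_index("participant_id").loc[pids, selection.accepted])
    return OutcomeRun(result=result, selection=selection, ols=ols,
                      logistic=logistic, folds=folds)
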