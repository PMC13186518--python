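"""Leave-one-subject-out gradient-boosted classification of day-level features.

Each fold holds out all day rows of one participant; the remaining
participants' rows train an XGBoost classifier on the selected features.  A
Yeo-Johnson power transform (with standardization) is fitted on the training
rows only and applied to the held-out rows.  Hyperparameters are tuned per
fold by randomized search over a small-data grid, scored by day-level ROC AUC
under participant-grouped, label-stratified 3-fold inner CV.  The held-out
participant's day probabilities are averaged into a single person-level
predicted probability.

A programmatic leakage guard asserts on every fold that no held-out
participant's rows entered training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.preprocessing import PowerTransformer

__all__ = [
    "FoldResult",
    "SearchSpace",
    "LosoConfig",
    "yeo_johnson_fit",
    "yeo_johnson_apply",
    "random_search",
    "loso_cv",
    "LeakageError",
]


class LeakageError(RuntimeError):
    """Raised when a held-out participant's rows are found in training data."""


@dataclass
class SearchSpace:
    """Randomized-search grid for the boosted-tree ensemble.

    Small-data-appropriate ranges; each draw picks one value per key
    uniformly at random.
    """

    max_depth: Sequence[int] = (2, 3, 4)
    learning_rate: Sequence[float] = (0.01, 0.05, 0.1, 0.3)
    n_estimators: Sequence[int] = (25, 50, 100, 200)
    subsample: Sequence[float] = (0.7, 1.0)
    colsample_bytree: Sequence[float] = (0.7, 1.0)
    min_child_weight: Sequence[float] = (1, 5)

    def draw(self, rng: np.random.Generator) -> dict:
        return {
            name: values[rng.integers(len(values))]
            for name, values in vars(self).items()
        }

    def defaults(self) -> dict:
        return {name: values[0] for name, values in vars(self).items()}


@dataclass
class LosoConfig:
    """LOSO run parameters.

    n_search_draws : random hyperparameter draws per fold (default 25).
    inner_folds : grouped stratified folds for tuning (default 3).
    pool_transform : if True, fit the Yeo-Johnson transform on training and
        test rows pooled (replicating a potentially leaky variant); default
        False fits on training rows only.
    """

    search_space: SearchSpace = field(default_factory=SearchSpace)
    n_search_draws: int = 25
    inner_folds: int = 3
    pool_transform: bool = False


@dataclass
class FoldResult:
    """One LOSO fold: held-out participant, day and person probabilities."""

    held_out_participant: str
    day_probabilities: np.ndarray
    person_probability: float
    booster: xgb.Booster
    feature_names: list[str]
    best_params: dict
    test_X: np.ndarray | None = None  # transformed held-out feature matrix
    valid: bool = True


def yeo_johnson_fit(columns: pd.DataFrame) -> PowerTransformer:
    """Fit per-column Yeo-Johnson transforms (lambda by maximum likelihood).

    Constant columns get lambda = 1 (identity) with a warning.
    """
    pt = PowerTransformer(method="yeo-johnson", standardize=True)
    const = [c for c in columns.columns if columns[c].nunique() <= 1]
    if const:
        warnings.warn(f"constant columns {const}: lambda fixed at 1", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pt.fit(columns.to_numpy(dtype=float))
    for i, c in enumerate(columns.columns):
        if c in const:
            pt.lambdas_[i] = 1.0
    return pt


def yeo_johnson_apply(spec: PowerTransformer, columns: pd.DataFrame) -> np.ndarray:
    return spec.transform(columns.to_numpy(dtype=float))


def _fit_xgb(X: np.ndarray, y: np.ndarray, params: dict, seed: int) -> xgb.XGBClassifier:
    # base_score is pinned at 0.5: letting xgboost estimate it from the
    # training labels imprints the training split's class prevalence on all
    # predictions, which under leave-one-subject-out is anticorrelated with
    # the held-out label and biases null-model AUC below chance
    model = xgb.XGBClassifier(
        objective="binary:logistic",
        base_score=0.5,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        **params,
    )
    model.fit(X, y)
    return model


def _day_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # Mann-Whitney AUC, ties counted 1/2 (local copy to avoid a cycle with
    # the evaluation module).
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))


def random_search(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    space: SearchSpace,
    n_draws: int,
    seed: int,
    inner_folds: int = 3,
) -> dict:
    """Pick the parameter draw maximizing inner grouped-CV day-level AUC.

    Deterministic given the seed.  With an empty effective grid or a single
    draw the result is that draw.  Inner folds group by participant and
    stratify on the label so every validation fold sees both classes where
    feasible.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws = [space.draw(rng) for _ in range(n_draws)]
    # dedupe while preserving order: the grid is tiny
    seen, unique_draws = set(), []
    for d in draws:
        key = tuple(sorted(d.items()))
        if key not in seen:
            seen.add(key)
            unique_draws.append(d)
    if len(unique_draws) == 1:
        return unique_draws[0]

    n_splits = min(inner_folds, len(np.unique(groups)))
    if n_splits < 2:
        return unique_draws[0]
    cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**31))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        splits = list(cv.split(X, y, groups))

    best_params, best_score = unique_draws[0], -np.inf
    for params in unique_draws:
        scores = []
        for tr, va in splits:
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                continue
            model = _fit_xgb(X[tr], y[tr], params, seed)
            scores.append(_day_auc(model.predict_proba(X[va])[:, 1], y[va]))
        score = float(np.nanmean(scores)) if scores else -np.inf
        if score > best_score:
            best_score, best_params = score, params
    return best_params


def loso_cv(
    day_rows: pd.DataFrame,
    labels_by_participant: dict[str, int],
    selected_features: list[str] | dict[str, list[str]],
    seed: int,
    config: LosoConfig | None = None,
) -> list[FoldResult]:
    """Leave-one-subject-out cross-validation over day rows.

    ``day_rows`` must carry a ``participant_id`` column plus the selected
    feature columns; each day row inherits its participant's binary label.
    ``selected_features`` is either one feature list used in every fold
    (full-sample selection) or a mapping held-out participant -> feature
    list (within-fold selection).  Returns one :class:`FoldResult` per
    participant present in both ``day_rows`` and ``labels_by_participant``.
    """
    cfg = config or LosoConfig()
    rows = day_rows[day_rows["participant_id"].isin(labels_by_participant)].copy()
    participants = sorted(rows["participant_id"].unique())
    if len(participants) < 2:
        raise ValueError("LOSO needs at least 2 participants")
    y_all = rows["participant_id"].map(labels_by_participant).to_numpy(dtype=int)
    if len(np.unique(y_all)) < 2:
        raise ValueError("need at least one positive and one negative participant")

    results: list[FoldResult] = []
    for i, held_out in enumerate(participants):
        test_mask = (rows["participant_id"] == held_out).to_numpy()
        train = rows[~test_mask]
        test = rows[test_mask]
        overlap = set(train["participant_id"]) & {held_out}
        if overlap:
            raise LeakageError(f"held-out participant {held_out} present in training")
        y_tr = train["participant_id"].map(labels_by_participant).to_numpy(dtype=int)
        valid = len(np.unique(y_tr)) == 2
        feats = (
            selected_features[held_out]
            if isinstance(selected_features, dict)
            else list(selected_features)
        )

        fold_seed = (seed * 100003 + i * 7919) % (2**31)
        if cfg.pool_transform:
            spec = yeo_johnson_fit(rows[feats])
        else:
            spec = yeo_johnson_fit(train[feats])
        X_tr = yeo_johnson_apply(spec, train[feats])
        X_te = yeo_johnson_apply(spec, test[feats])

        if valid:
            params = random_search(
                X_tr,
                y_tr,
                train["participant_id"].to_numpy(),
                cfg.search_space,
                cfg.n_search_draws,
                fold_seed,
                cfg.inner_folds,
            )
            model = _fit_xgb(X_tr, y_tr, params, fold_seed)
            booster = model.get_booster()
            booster.feature_names = list(feats)
            day_probs = model.predict_proba(X_te)[:, 1].astype(float)
        else:
            params = {}
            booster = None
            day_probs = np.full(len(test), np.nan)
        results.append(
            FoldResult(
                held_out_participant=held_out,
                day_probabilities=day_probs,
                person_probability=float(np.mean(day_probs)),
                booster=booster,
                feature_names=list(feats),
                best_params=params,
                test_X=X_te,
                valid=valid,
            )
        )
    return results


def person_scores(folds: list[FoldResult]) -> dict[str, float]:
    """Person-level predicted probabilities keyed by participant."""
    return {f.held_out_participant: f.person_probability for f in folds if f.valid}


def check_no_leakage(
    folds: list[FoldResult], day_rows: pd.DataFrame, labels_by_participant: dict[str, int]
) -> bool:
    """Structural leakage re-check: every fold excludes its held-out subject.

    LOSO folds partition participants, so it suffices that each fold's
    held-out id appears exactly once across folds and that each fold's
    person probability was computed only from that participant's rows (row
    counts must match).
    """
    ids = [f.held_out_participant for f in folds]
    if len(set(ids)) != len(ids):
        raise LeakageError("a participant was held out more than once")
    counts = day_rows.groupby("participant_id").size()
    for f in folds:
        if f.held_out_participant not in labels_by_participant:
            raise LeakageError(f"unknown participant {f.held_out_participant}")
        if len(f.day_probabilities) != counts[f.held_out_participant]:
            raise LeakageError(
                f"fold for {f.held_out_participant} scored "
                f"{len(f.day_probabilities)} rows, expected "
                f"{counts[f.held_out_participant]}"
            )
    return True
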