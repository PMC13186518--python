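"""Person-level model evaluation: AUC with bootstrap CI, confusion metrics,
bootstrap AUC comparison between models, and tree-ensemble attributions.

The AUC point estimate uses the Mann-Whitney formulation (ties counted 1/2);
its 95% CI comes from a seeded percentile bootstrap over persons (2000
resamples).  Two models are compared by resampling persons with replacement
(jointly where the cohorts coincide), recomputing both AUCs per iteration,
and reading a two-sided p-value off the difference distribution with the
(count + 1) / (iterations + 1) small-sample correction.

Per-feature attributions are exact TreeSHAP values queried from the boosted
ensemble on each fold's held-out rows; local accuracy (attributions + base
value = margin output) is asserted to 1e-6.  Information gain is the total
split gain per feature, averaged over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .loso_model import FoldResult

__all__ = [
    "ModelRunResult",
    "roc_auc_point",
    "roc_auc",
    "confusion_metrics",
    "bootstrap_auc_compare",
    "attribution_summary",
]


@dataclass
class ModelRunResult:
    """Evaluation summary for one outcome definition."""

    outcome_name: str
    person_scores: dict[str, float]
    labels: dict[str, int]
    auc: float
    auc_ci: tuple[float, float]
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float | None
    f1: float
    mean_abs_shap: dict[str, float] = field(default_factory=dict)
    mean_gain: dict[str, float] = field(default_factory=dict)
    selected_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "outcome_name": self.outcome_name,
            "person_scores": self.person_scores,
            "labels": self.labels,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "mean_abs_shap": self.mean_abs_shap,
            "mean_gain": self.mean_gain,
            "selected_features": self.selected_features,
        }

    def format_table(self) -> str:
        """Human-readable metrics block, one model per column of use."""
        lines = [
            f"Model: {self.outcome_name}",
            f"  AUC (95% CI): {self.auc:.2f} ({self.auc_ci[0]:.2f}-{self.auc_ci[1]:.2f})",
            f"  Accuracy:    {self.accuracy:.2f}",
            f"  Sensitivity: {self.sensitivity:.2f}",
            f"  Specificity: {self.specificity:.2f}",
            "  Precision:   "
            + ("n/a" if self.precision is None else f"{self.precision:.2f}"),
            f"  F1-score:    {self.f1:.2f}",
        ]
        if self.mean_abs_shap:
            lines.append("  Mean |SHAP|:")
            for name, v in self.mean_abs_shap.items():
                lines.append(f"    {name}: {v:.3f}")
        if self.mean_gain:
            lines.append("  Mean information gain:")
            for name, v in self.mean_gain.items():
                lines.append(f"    {name}: {v:.3f}")
        return "\n".join(lines)


def roc_auc_point(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney ROC AUC; ties between a positive and a negative count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float, float]:
    """(AUC, CI low, CI high) with a percentile bootstrap over persons."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = roc_auc_point(scores, labels)
    rng = np.random.default_rng(seed)
    n = len(scores)
    boots = []
    for _ in range(n_boot):
        for _retry in range(100):
            idx = rng.integers(n, size=n)
            if len(np.unique(labels[idx])) == 2:
                boots.append(roc_auc_point(scores[idx], labels[idx]))
                break
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(boots, [alpha, 1 - alpha])
    return auc, float(lo), float(hi)


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity, precision and F1 at a threshold.

    Predicted positive iff score >= threshold.  With no predicted positives,
    precision is ``None`` (undefined) and F1 is 0 by convention.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("confusion metrics need both classes present")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    if precision is not None and (precision + sensitivity) > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        f1 = 0.0
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "f1": f1,
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }


def bootstrap_auc_compare(
    scores_a: dict[str, float],
    scores_b: dict[str, float],
    labels_a: dict[str, int],
    labels_b: dict[str, int],
    iterations: int = 2000,
    seed: int = 0,
    max_retries: int = 100,
) -> float:
    """Two-sided bootstrap p-value for the AUC difference of two models.

    Participants are resampled with replacement per iteration — jointly for
    participants the two cohorts share, independently for the remainder —
    and both AUCs are recomputed on the resample.  p = 2 * min(P(diff <= 0),
    P(diff >= 0)) with the (count + 1) / (iterations + 1) correction,
    capped at 1.  Degenerate single-class resamples are redrawn up to
    ``max_retries`` times.
    """
    ids_a = sorted(scores_a)
    ids_b = sorted(scores_b)
    shared = sorted(set(ids_a) & set(ids_b))
    only_a = sorted(set(ids_a) - set(shared))
    only_b = sorted(set(ids_b) - set(shared))
    rng = np.random.default_rng(seed)

    def resample_cohort(shared_draw: list[str], only: list[str], ids: list[str]) -> list[str]:
        extra = [only[i] for i in rng.integers(len(only), size=len(only))] if only else []
        return [p for p in shared_draw if p in set(ids)] + extra

    n_le = 0  # diff <= 0
    n_ge = 0  # diff >= 0
    done = 0
    for _ in range(iterations):
        for _retry in range(max_retries):
            shared_draw = (
                [shared[i] for i in rng.integers(len(shared), size=len(shared))]
                if shared
                else []
            )
            draw_a = resample_cohort(shared_draw, only_a, ids_a)
            draw_b = resample_cohort(shared_draw, only_b, ids_b)
            la = np.array([labels_a[p] for p in draw_a])
            lb = np.array([labels_b[p] for p in draw_b])
            if len(np.unique(la)) == 2 and len(np.unique(lb)) == 2:
                sa = np.array([scores_a[p] for p in draw_a])
                sb = np.array([scores_b[p] for p in draw_b])
                diff = roc_auc_point(sa, la) - roc_auc_point(sb, lb)
                n_le += diff <= 0
                n_ge += diff >= 0
                done += 1
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
    p = 2.0 * min((n_le + 1) / (done + 1), (n_ge + 1) / (done + 1))
    return float(min(p, 1.0))


def attribution_summary(
    folds: list[FoldResult],
    atol: float = 1e-6,
) -> tuple[dict[str, float], dict[str, float]]:
    """(mean |SHAP|, mean total gain) per feature across folds' test rows.

    Attributions are exact TreeSHAP values on each fold's held-out
    (transformed) rows.  Local accuracy — per-row attributions plus base
    value equal the margin output — is asserted to ``atol`` on every row.
    Both maps are sorted by descending value.  Features never split on
    receive gain 0.
    """
    all_names: list[str] = []
    for fold in folds:
        for f in fold.feature_names:
            if f not in all_names:
                all_names.append(f)
    abs_sums = {f: 0.0 for f in all_names}
    n_rows = 0
    gain_sums = {f: 0.0 for f in all_names}
    n_folds = 0
    for fold in folds:
        if not fold.valid or fold.booster is None or fold.test_X is None:
            continue
        X = np.asarray(fold.test_X, dtype=float)
        dm = xgb.DMatrix(X, feature_names=fold.feature_names)
        contribs = fold.booster.predict(dm, pred_contribs=True)
        margins = fold.booster.predict(dm, output_margin=True)
        recon = contribs.sum(axis=1)
        if not np.allclose(recon, margins, atol=atol):
            raise AssertionError(
                "attribution local accuracy violated: max error "
                f"{np.max(np.abs(recon - margins)):.3g}"
            )
        for j, f in enumerate(fold.feature_names):
            abs_sums[f] += float(np.sum(np.abs(contribs[:, j])))
        n_rows += len(X)
        gains = fold.booster.get_score(importance_type="total_gain")
        for f in fold.feature_names:
            gain_sums[f] += float(gains.get(f, 0.0))
        n_folds += 1
    if n_rows == 0 or n_folds == 0:
        raise ValueError("no valid folds with test rows")
    mean_shap = {f: abs_sums[f] / n_rows for f in all_names}
    mean_gain = {f: gain_sums[f] / n_folds for f in all_names}
    order_shap = sorted(mean_shap, key=lambda f: -mean_shap[f])
    order_gain = sorted(mean_gain, key=lambda f: -mean_gain[f])
    return (
        {f: mean_shap[f] for f in order_shap},
        {f: mean_gain[f] for f in order_gain},
    )
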