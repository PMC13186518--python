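"""Univariate F-score feature selection with correlation pruning.

Daily features are first aggregated to one row per participant (within-person
arithmetic mean).  Each feature is then ranked by the one-way two-group ANOVA
F statistic against the binary outcome; for two groups this equals the
squared pooled-variance t statistic.  Candidates are accepted greedily by
descending F, skipping any feature whose absolute Pearson correlation with an
already-accepted feature is >= 0.70, until k (default 3) are accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SelectionReport", "aggregate_person", "f_score", "select_top_k"]

#: Sentinel replacing an infinite F under perfect separation (zero
#: within-group variance with distinct group means).
PERFECT_SEPARATION_F = 1e12


@dataclass
class SelectionReport:
    """Outcome of top-k univariate selection for one outcome definition."""

    outcome_name: str
    f_scores: dict[str, float]
    accepted: list[str]
    rejected_for_correlation: list[tuple[str, str, float]] = field(default_factory=list)
    perfectly_separated: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "outcome_name": self.outcome_name,
            "f_scores": self.f_scores,
            "accepted": self.accepted,
            "rejected_for_correlation": [
                {"feature": a, "conflicts_with": b, "r": r}
                for a, b, r in self.rejected_for_correlation
            ],
            "perfectly_separated": self.perfectly_separated,
        }


def aggregate_person(day_rows: pd.DataFrame, feature_names: list[str]) -> pd.DataFrame:
    """Within-person mean of daily features; one row per participant.

    Participants with zero retained rows are simply absent; a warning is not
    possible here since they never appear in ``day_rows``.
    """
    agg = day_rows.groupby("participant_id", sort=True)[feature_names].mean()
    return agg.reset_index()


def f_score(values: np.ndarray, labels: np.ndarray) -> float:
    """One-way two-group ANOVA F = between-group MS / within-group MS.

    Equals the squared pooled-variance two-sample t statistic.  Zero
    within-group variance with differing means yields the sentinel
    ``PERFECT_SEPARATION_F``; identical values everywhere yield 0.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    groups = [x[y == g] for g in np.unique(y)]
    if len(groups) < 2:
        raise ValueError("f_score needs both classes present")
    k = len(groups)
    n = len(x)
    grand = x.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    if ssw == 0:
        return 0.0 if ssb == 0 else PERFECT_SEPARATION_F
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def select_top_k(
    person_table: pd.DataFrame,
    labels: np.ndarray,
    feature_names: list[str],
    outcome_name: str = "outcome",
    k: int = 3,
    r_max: float = 0.70,
) -> SelectionReport:
    """Greedy top-k selection by descending F with pairwise |r| < r_max.

    Ties in F are broken lexicographically by feature name for determinism.
    If fewer than k acceptable features exist, the report contains what was
    found and a warning is emitted.
    """
    labels = np.asarray(labels)
    scores = {}
    separated = []
    for name in feature_names:
        f = f_score(person_table[name].to_numpy(), labels)
        scores[name] = f
        if f >= PERFECT_SEPARATION_F:
            separated.append(name)
    ranked = sorted(scores, key=lambda name: (-scores[name], name))

    accepted: list[str] = []
    rejected: list[tuple[str, str, float]] = []
    for name in ranked:
        if len(accepted) >= k:
            break
        conflict = None
        for prev in accepted:
            r = float(np.corrcoef(person_table[name], person_table[prev])[0, 1])
            if np.isnan(r):
                r = 0.0
            if abs(r) >= r_max:
                conflict = (name, prev, r)
                break
        if conflict is None:
            accepted.append(name)
        else:
            rejected.append(conflict)
    if len(accepted) < k:
        warnings.warn(
            f"only {len(accepted)} of {k} requested features are mutually "
            f"acceptable at |r| < {r_max}",
            stacklevel=2,
        )
    return SelectionReport(
        outcome_name=outcome_name,
        f_scores=scores,
        accepted=accepted,
        rejected_for_correlation=rejected,
        perfectly_separated=separated,
    )
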