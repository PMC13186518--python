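"""AUC, confusion metrics, bootstrap comparison, and tree attributions."""

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb
from sklearn.metrics import roc_auc_score

from actiphen.evaluation import (
    attribution_summary,
    bootstrap_auc_compare,
    confusion_metrics,
    roc_auc,
    roc_auc_point,
)
from actiphen.loso_model import FoldResult


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.8, 0.3], [1, 0, 0], 1.0),
            ([0.8, 0.9, 0.3], [1, 0, 0], 0.5),
            ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),  # all ties count 1/2
            ([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], 0.0),
        ],
    )
    def test_pair_enumeration_examples(self, scores, labels, expected):
        assert roc_auc_point(np.array(scores), np.array(labels)) == expected

    def test_matches_trapezoidal_oracle(self, rng):
        """Mann-Whitney formulation equals sklearn's trapezoidal ROC area."""
        for _ in range(25):
            scores = rng.normal(size=30).round(1)  # induce ties
            labels = rng.integers(0, 2, size=30)
            if len(np.unique(labels)) < 2:
                continue
            assert roc_auc_point(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_point(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 15), rng.normal(0, 1, 15)])
        labels = np.repeat([1, 0], 15)
        auc, lo, hi = roc_auc(scores, labels, seed=5)
        assert 0 <= lo <= auc <= hi <= 1
        assert hi - lo > 0


class TestConfusionMetrics:
    def _from_counts(self, tp, fn, tn, fp):
        scores = np.concatenate([
            np.ones(tp), np.zeros(fn), np.zeros(tn), np.ones(fp)
        ])
        labels = np.concatenate([
            np.ones(tp + fn, int), np.zeros(tn + fp, int)
        ])
        return confusion_metrics(scores, labels)

    @pytest.mark.parametrize(
        "counts, accuracy, precision, f1",
        [
            ((5, 3, 24, 1), 29 / 33, 5 / 6, 0.7143),
            ((8, 3, 18, 4), 26 / 33, 8 / 12, 0.6957),
            ((3, 4, 17, 9), 20 / 33, 3 / 12, 0.3158),
        ],
        ids=["sens5of8-spec24of25", "sens8of11-spec18of22", "sens3of7-spec17of26"],
    )
    def test_worked_examples_from_counts(self, counts, accuracy, precision, f1):
        m = self._from_counts(*counts)
        assert m["accuracy"] == pytest.approx(accuracy)
        assert m["precision"] == pytest.approx(precision)
        assert m["f1"] == pytest.approx(f1, abs=5e-5)

    def test_perfect_classifier(self):
        m = self._from_counts(5, 0, 5, 0)
        assert all(m[k] == 1.0 for k in
                   ("accuracy", "sensitivity", "specificity", "precision", "f1"))

    def test_no_predicted_positives(self):
        m = confusion_metrics(np.array([0.1, 0.2, 0.3]), np.array([1, 0, 0]))
        assert m["precision"] is None
        assert m["f1"] == 0.0

    def test_threshold_is_inclusive(self):
        m = confusion_metrics(np.array([0.5, 0.49]), np.array([1, 0]))
        assert m["tp"] == 1 and m["fp"] == 0


class TestBootstrapAucCompare:
    def _planted(self, rng, n=200, informative=True):
        labels = {f"p{i}": int(i < n // 2) for i in range(n)}
        if informative:
            scores = {p: labels[p] * 1.0 + rng.normal(0, 1e-3) for p in labels}
        else:
            scores = {p: rng.uniform() for p in labels}
        return scores, labels

    def test_identical_models_p_one(self, rng):
        scores, labels = self._planted(rng, n=40)
        p = bootstrap_auc_compare(scores, scores, labels, labels, seed=0)
        assert p == 1.0

    def test_planted_auc_gap_detected(self, rng):
        """AUC 1.0 vs 0.5 at n = 200 persons is significant at p < 0.01."""
        good, labels = self._planted(rng, n=200, informative=True)
        noise, _ = self._planted(rng, n=200, informative=False)
        p = bootstrap_auc_compare(good, noise, labels, labels, seed=1)
        assert p < 0.01

    def test_symmetric_in_model_order(self, rng):
        a, labels = self._planted(rng, n=60, informative=True)
        b, _ = self._planted(rng, n=60, informative=False)
        p_ab = bootstrap_auc_compare(a, b, labels, labels, iterations=500, seed=2)
        p_ba = bootstrap_auc_compare(b, a, labels, labels, iterations=500, seed=2)
        assert p_ab == pytest.approx(p_ba)

    def test_disjoint_cohorts_supported(self, rng):
        a, la = self._planted(rng, n=30)
        b_raw, lb_raw = self._planted(rng, n=30)
        b = {f"q{i}": v for i, (_, v) in enumerate(sorted(b_raw.items()))}
        lb = {f"q{i}": v for i, (_, v) in enumerate(sorted(lb_raw.items()))}
        p = bootstrap_auc_compare(a, b, la, lb, iterations=200, seed=3)
        assert 0 < p <= 1


def _single_split_fold(rng):
    """Depth-1, single-tree model on one informative feature of two."""
    X = np.column_stack([np.repeat([0.0, 1.0], 20), rng.normal(size=40)])
    y = np.repeat([0, 1], 20)
    model = xgb.XGBClassifier(
        n_estimators=1, max_depth=1, learning_rate=1.0, base_score=0.5,
        reg_lambda=0.0, n_jobs=1, random_state=0,
    )
    model.fit(X, y)
    booster = model.get_booster()
    booster.feature_names = ["informative", "noise"]
    return FoldResult(
        held_out_participant="p0",
        day_probabilities=model.predict_proba(X)[:, 1],
        person_probability=0.5,
        booster=booster,
        feature_names=["informative", "noise"],
        best_params={},
        test_X=X,
    )


class TestAttributionSummary:
    def test_single_split_attributions_by_hand(self, rng):
        """With one depth-1 tree, each row's attribution on the split feature
        equals its leaf margin minus the base value, and the unused feature
        gets zero |SHAP| and zero gain."""
        fold = _single_split_fold(rng)
        mean_shap, mean_gain = attribution_summary([fold])
        tree = fold.booster.trees_to_dataframe()
        leaves = tree[tree.Feature == "Leaf"]["Gain"].to_numpy()
        assert len(leaves) == 2
        # contributions are the leaf-margin deviations from the tree's
        # (cover-weighted, here balanced) expected margin
        expected = np.mean(np.abs(leaves - leaves.mean()))
        assert mean_shap["informative"] == pytest.approx(expected, abs=1e-6)
        assert mean_shap["noise"] == 0.0
        assert mean_gain["noise"] == 0.0
        assert mean_gain["informative"] > 0

    def test_local_accuracy_enforced(self, rng):
        fold = _single_split_fold(rng)
        margins = fold.booster.predict(
            xgb.DMatrix(fold.test_X, feature_names=fold.feature_names),
            output_margin=True,
        )
        contribs = fold.booster.predict(
            xgb.DMatrix(fold.test_X, feature_names=fold.feature_names),
            pred_contribs=True,
        )
        assert np.allclose(contribs.sum(axis=1), margins, atol=1e-6)

    def test_report_sorted_descending(self, dx_run):
        shap_vals = list(dx_run.result.mean_abs_shap.values())
        gain_vals = list(dx_run.result.mean_gain.values())
        assert shap_vals == sorted(shap_vals, reverse=True)
        assert gain_vals == sorted(gain_vals, reverse=True)
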