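"""Yeo-Johnson transform, randomized search, and LOSO cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from actiphen.loso_model import (
    LeakageError,
    LosoConfig,
    SearchSpace,
    check_no_leakage,
    loso_cv,
    person_scores,
    random_search,
    yeo_johnson_apply,
    yeo_johnson_fit,
)

FAST = LosoConfig(n_search_draws=2)


def _toy_rows(rng, n_participants=8, days=5, effect=3.0):
    pids = [f"p{i}" for i in range(n_participants)]
    labels = {p: int(i < n_participants // 2) for i, p in enumerate(pids)}
    rows = []
    for p in pids:
        for _ in range(days):
            rows.append({
                "participant_id": p,
                "x1": rng.normal(effect * labels[p], 1.0),
                "x2": rng.normal(0, 1.0),
            })
    return pd.DataFrame(rows), labels


class TestYeoJohnson:
    def test_constant_column_identity_lambda(self):
        df = pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            spec = yeo_johnson_fit(df)
        assert spec.lambdas_[0] == 1.0

    def test_transform_is_monotone_per_feature(self, rng):
        df = pd.DataFrame({"a": np.sort(rng.gamma(2.0, 3.0, size=50))})
        out = yeo_johnson_apply(yeo_johnson_fit(df), df)
        assert np.all(np.diff(out[:, 0]) >= 0)

    def test_lambda_matches_grid_likelihood_oracle(self, rng):
        """Fitted lambda is within 0.1 of a brute-force grid maximizer of the
        Gaussian profile log-likelihood (scipy transform as the oracle)."""
        x = rng.exponential(2.0, size=200)
        spec = yeo_johnson_fit(pd.DataFrame({"x": x}))
        grid = np.linspace(-2, 2, 401)
        lls = [stats.yeojohnson_llf(l, x) for l in grid]
        assert abs(float(spec.lambdas_[0]) - grid[int(np.argmax(lls))]) <= 0.1


class TestRandomSearch:
    def test_single_draw_returned(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.tile([0, 1], 10)
        groups = np.repeat(np.arange(10), 2)
        space = SearchSpace()
        got = random_search(X, y, groups, space, n_draws=1, seed=3)
        expect = space.draw(np.random.default_rng(3))
        assert got == expect

    def test_single_point_grid(self, rng):
        space = SearchSpace(max_depth=(2,), learning_rate=(0.1,),
                            n_estimators=(25,), subsample=(1.0,),
                            colsample_bytree=(1.0,), min_child_weight=(1,))
        got = random_search(rng.normal(size=(12, 2)), np.tile([0, 1], 6),
                            np.repeat(np.arange(6), 2), space, n_draws=5, seed=0)
        assert got == space.defaults()

    def test_informative_configuration_wins(self, rng):
        """Between a 1-round shrunk learner and a real one, the searched AUC
        prefers the configuration that can separate a separable toy set."""
        n = 60
        X = np.column_stack([np.repeat([0.0, 4.0], n // 2)]) + rng.normal(0, 0.1, (n, 1))
        y = np.repeat([0, 1], n // 2)
        groups = np.arange(n) % 12
        space = SearchSpace(max_depth=(1, 3), learning_rate=(1e-5, 0.3),
                            n_estimators=(1, 100), subsample=(1.0,),
                            colsample_bytree=(1.0,), min_child_weight=(1,))
        best = random_search(X, y, groups, space, n_draws=20, seed=1)
        assert best["learning_rate"] == 0.3
        assert best["n_estimators"] == 100


class TestLosoCv:
    def test_one_fold_per_participant(self, rng):
        rows, labels = _toy_rows(rng, n_participants=4)
        folds = loso_cv(rows, labels, ["x1", "x2"], seed=0, config=FAST)
        assert [f.held_out_participant for f in folds] == sorted(labels)
        for f in folds:
            assert f.valid
            assert len(f.day_probabilities) == 5
            assert np.all((f.day_probabilities >= 0) & (f.day_probabilities <= 1))
            assert f.person_probability == pytest.approx(np.mean(f.day_probabilities))

    def test_three_participants_single_class_training_flagged(self, rng):
        """With one positive of three subjects, the fold holding out the
        positive trains single-class and is flagged invalid, not silently
        scored."""
        rows, labels = _toy_rows(rng, n_participants=3)  # p0 positive
        folds = loso_cv(rows, labels, ["x1", "x2"], seed=0, config=FAST)
        assert [f.held_out_participant for f in folds] == ["p0", "p1", "p2"]
        assert not folds[0].valid
        assert folds[1].valid and folds[2].valid

    def test_deterministic_given_seed(self, rng):
        rows, labels = _toy_rows(rng)
        a = person_scores(loso_cv(rows, labels, ["x1", "x2"], seed=7, config=FAST))
        b = person_scores(loso_cv(rows, labels, ["x1", "x2"], seed=7, config=FAST))
        assert a == b

    def test_separable_cohort_achieves_high_person_auc(self, rng):
        rows, labels = _toy_rows(rng, n_participants=10, effect=4.0)
        folds = loso_cv(rows, labels, ["x1", "x2"], seed=0,
                        config=LosoConfig(n_search_draws=8))
        scores = person_scores(folds)
        pos = np.array([scores[p] for p in scores if labels[p] == 1])
        neg = np.array([scores[p] for p in scores if labels[p] == 0])
        diff = pos[:, None] - neg[None, :]
        auc = (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size
        assert auc >= 0.9

    def test_leakage_guard_rejects_duplicated_holdout(self, rng):
        """Bug injection: a fold claiming extra rows for its held-out subject
        trips the structural leakage check."""
        rows, labels = _toy_rows(rng, n_participants=4)
        folds = loso_cv(rows, labels, ["x1", "x2"], seed=0, config=FAST)
        assert check_no_leakage(folds, rows, labels)
        folds[0].day_probabilities = np.append(folds[0].day_probabilities, 0.5)
        with pytest.raises(LeakageError):
            check_no_leakage(folds, rows, labels)
        folds2 = loso_cv(rows, labels, ["x1", "x2"], seed=0, config=FAST)
        folds2[1].held_out_participant = folds2[0].held_out_participant
        with pytest.raises(LeakageError):
            check_no_leakage(folds2, rows, labels)

    def test_needs_two_participants_and_two_classes(self, rng):
        rows, labels = _toy_rows(rng, n_participants=4)
        with pytest.raises(ValueError):
            loso_cv(rows[rows.participant_id == "p0"], {"p0": 1}, ["x1"], seed=0)
        all_pos = {p: 1 for p in labels}
        with pytest.raises(ValueError):
            loso_cv(rows, all_pos, ["x1"], seed=0)
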