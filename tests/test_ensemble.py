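"""Result matrix, classifier clustering, CEFS selection and voting."""

import itertools

import numpy as np
import pytest

from cytosel import (
    SelectiveEnsembleClassifier,
    build_result_matrix,
    cefs_select,
    cluster_classifiers,
    committee_accuracy,
    default_pool,
    mean_pairwise_agreement,
)
from cytosel.ensemble import BaseLearnerSpec
from sklearn.dummy import DummyClassifier
from sklearn.linear_model import LogisticRegression


def _separable_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-3, 0.5, (n // 2, 2)), rng.normal(3, 0.5, (n // 2, 2))])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestResultMatrix:
    def test_default_pool_has_18_distinct_members(self):
        pool = default_pool()
        assert len(pool) == 18
        assert len({spec.name for spec in pool}) == 18

    def test_constant_predictor_row_accuracy_half_on_balanced_data(self):
        X, y = _separable_data()
        pool = [
            BaseLearnerSpec("zero", "constant", lambda s: DummyClassifier(strategy="most_frequent")),
            BaseLearnerSpec("logit", "logistic", lambda s: LogisticRegression()),
        ]
        R, names, fitted = build_result_matrix(pool, X, y, mode="resubstitution")
        assert R[names.index("zero")].mean() == 0.5

    def test_perfect_learner_row_is_all_ones(self):
        X, y = _separable_data()
        pool = [
            BaseLearnerSpec("logit", "logistic", lambda s: LogisticRegression()),
            BaseLearnerSpec("zero", "constant", lambda s: DummyClassifier(strategy="most_frequent")),
        ]
        R, names, _ = build_result_matrix(pool, X, y, mode="resubstitution")
        assert R[names.index("logit")].all()

    def test_margin_classifier_beats_constant_on_separable_data(self):
        X, y = _separable_data()
        pool = [
            BaseLearnerSpec("zero", "constant", lambda s: DummyClassifier(strategy="most_frequent")),
            BaseLearnerSpec("logit", "logistic", lambda s: LogisticRegression()),
        ]
        R, names, _ = build_result_matrix(pool, X, y, mode="out_of_fold", seed=0)
        assert R[names.index("logit")].mean() > R[names.index("zero")].mean()

    def test_binary_entries_only(self):
        X, y = _separable_data()
        R, _, _ = build_result_matrix(default_pool()[:4], X, y, seed=0)
        assert set(np.unique(R)) <= {0, 1}

    def test_failing_learner_dropped_but_two_required(self):
        class Broken:
            def fit(self, X, y):
                raise RuntimeError("boom")

        X, y = _separable_data()
        pool = [
            BaseLearnerSpec("broken", "x", lambda s: Broken()),
            BaseLearnerSpec("logit", "logistic", lambda s: LogisticRegression()),
            BaseLearnerSpec("zero", "constant", lambda s: DummyClassifier(strategy="most_frequent")),
        ]
        with pytest.warns(UserWarning, match="broken"):
            R, names, _ = build_result_matrix(pool, X, y, mode="resubstitution")
        assert names == ["logit", "zero"]
        with pytest.raises(ValueError, match="fewer than 2"):
            with pytest.warns(UserWarning):
                build_result_matrix(pool[:1] * 2, X, y, mode="resubstitution")


class TestClusterClassifiers:
    def test_identical_rows_share_a_cluster(self):
        row = np.array([1, 0, 1, 1, 0, 1, 0, 0])
        R = np.vstack([row, row, 1 - row])
        labels = cluster_classifiers(R, K=2, seed=0)
        assert labels[0] == labels[1]

    def test_complementary_rows_split(self):
        row = np.array([1, 0, 1, 1, 0, 1, 0, 0])
        R = np.vstack([row, 1 - row])
        labels = cluster_classifiers(R, K=2, seed=0)
        assert labels[0] != labels[1]

    def test_k_capped_at_pool_size(self):
        R = np.eye(3, 7, dtype=int)
        labels = cluster_classifiers(R, K=9, seed=0)
        assert len(set(labels)) == 3


class TestCefsSelect:
    def test_perfect_learner_meets_initial_target(self):
        R = np.array(
            [
                [1, 1, 1, 1, 1, 1],
                [1, 0, 1, 0, 1, 0],
                [0, 1, 0, 1, 0, 1],
            ]
        )
        clusters = cluster_classifiers(R, K=3, seed=0)
        sel = cefs_select(clusters, R)
        assert 0 in sel.chosen
        assert sel.achieved_accuracy == 1.0

    def test_duplicate_pool_selects_single_member(self):
        row = np.array([1, 1, 0, 1, 0, 1])
        R = np.vstack([row] * 5)
        clusters = cluster_classifiers(R, K=3, seed=0)
        sel = cefs_select(clusters, R)
        assert len(sel.chosen) == 1

    def test_committee_accuracy_matches_exhaustive_vote_enumeration(self):
        """Every committee subset of a 3-learner toy matrix scored by
        explicit per-sample vote counting."""
        R = np.array([[1, 1, 1, 0], [1, 0, 1, 1], [0, 1, 1, 1]])
        acc = R.mean(axis=1)

        def brute(members):
            top = members[int(np.argmax(acc[members]))]
            correct = 0
            for j in range(R.shape[1]):
                votes_right = sum(R[i, j] for i in members)
                votes_wrong = len(members) - votes_right
                if votes_right > votes_wrong:
                    correct += 1
                elif votes_right == votes_wrong and R[top, j]:
                    correct += 1
            return correct / R.shape[1]

        for size in (1, 2, 3):
            for members in itertools.combinations(range(3), size):
                members = list(members)
                assert committee_accuracy(R, members, acc) == brute(members)

    def test_selection_never_below_seed_accuracy(self):
        rng = np.random.default_rng(5)
        R = (rng.random((8, 30)) > 0.4).astype(int)
        clusters = cluster_classifiers(R, K=4, seed=1)
        sel = cefs_select(clusters, R)
        best_single = R.mean(axis=1).max()
        assert sel.achieved_accuracy >= best_single

    def test_agreement_of_singleton_is_one(self):
        R = np.array([[1, 0, 1], [0, 1, 1]])
        assert mean_pairwise_agreement(R, [0]) == 1.0
        assert mean_pairwise_agreement(R, [0, 1]) == pytest.approx(1 / 3)


class _Const:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def _handmade_model(votes, accuracies):
    model = SelectiveEnsembleClassifier(pool=[])
    model.estimators_ = [_Const(v) for v in votes]
    model.learner_names_ = [f"c{i}" for i in range(len(votes))]
    model.chosen_ = list(range(len(votes)))
    model.chosen_names_ = model.learner_names_
    model.learner_accuracy_ = np.array(accuracies)
    model.achieved_accuracy_ = max(accuracies)
    model.classes_ = np.array([0, 1])
    model._fitted = True
    return model


class TestPredict:
    def test_unanimous_committee(self):
        model = _handmade_model([1, 1, 1], [0.9, 0.8, 0.7])
        labels, frac = model.predict_with_votes(np.zeros((4, 2)))
        assert (labels == 1).all()
        assert (frac == 1.0).all()

    def test_strict_majority(self):
        model = _handmade_model([1, 1, 0], [0.9, 0.8, 0.7])
        labels, frac = model.predict_with_votes(np.zeros((2, 2)))
        assert (labels == 1).all()
        assert np.allclose(frac, 2 / 3)

    def test_split_vote_follows_most_accurate_member(self):
        model = _handmade_model([0, 1], [0.9, 0.6])
        labels, frac = model.predict_with_votes(np.zeros((3, 2)))
        assert (labels == 0).all()
        assert np.allclose(frac, 0.5)

        model = _handmade_model([0, 1], [0.6, 0.9])
        labels, _ = model.predict_with_votes(np.zeros((3, 2)))
        assert (labels == 1).all()

    def test_unfitted_model_errors(self):
        model = SelectiveEnsembleClassifier(pool=[])
        with pytest.raises(RuntimeError, match="not fitted"):
            model.predict(np.zeros((1, 2)))


class TestEndToEndFit:
    def test_fit_predict_on_separable_data(self):
        X, y = _separable_data(n=80, seed=3)
        model = SelectiveEnsembleClassifier(
            pool=default_pool()[:6], k_clusters=3, seed=3
        ).fit(X, y)
        assert len(model.chosen_) >= 1
        assert set(model.chosen_names_) <= {s.name for s in default_pool()[:6]}
        assert (model.predict(X) == y).mean() > 0.95

    def test_singleton_committee_equals_member_predictions(self):
        X, y = _separable_data(n=40, seed=1)
        model = SelectiveEnsembleClassifier(pool=default_pool()[:4], seed=1).fit(X, y)
        if len(model.chosen_) == 1:
            member = model.estimators_[model.chosen_[0]]
            np.testing.assert_array_equal(model.predict(X), member.predict(X))

    def test_save_load_roundtrip(self, tmp_path):
        X, y = _separable_data(n=40, seed=2)
        model = SelectiveEnsembleClassifier(pool=default_pool()[:4], seed=2).fit(X, y)
        path = tmp_path / "model.joblib"
        model.save(path, metadata={"feature_set": "120d"})
        loaded = SelectiveEnsembleClassifier.load(path)
        np.testing.assert_array_equal(model.predict(X), loaded.predict(X))
        assert loaded.metadata_["feature_set"] == "120d"
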