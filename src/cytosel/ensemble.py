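"""Clustering-based selective ensemble with circulating forward selection.

A pool of 18 heterogeneous base learners is fitted to the training set
and summarised by a binary *result matrix* R (R_ij = 1 iff learner i
classified sample j correctly). Learners are clustered by their
correctness patterns (K-means on the rows of R, K = 9 by default) so that
each cluster groups learners that make similar mistakes. The best learner
per cluster forms the candidate list, sorted by accuracy; a voting
committee (the *chosen classifiers*, CC) is then grown by circulating
forward selection: a candidate joins only when committee majority-vote
accuracy strictly rises AND mean pairwise agreement strictly falls (the
committee becomes more diverse), with the target accuracy relaxed in
steps of 0.05 from 1.0 until the committee meets it. Prediction is a
majority vote of CC, with ties broken by the most accurate member.

For binary labels the committee's vote on sample j is recoverable from R
alone: a wrong member votes the (single) other label, so the majority
vote is correct exactly when more members are correct than wrong, with
the tie falling to the top-accuracy member. Selection therefore operates
purely on R.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.cluster import KMeans
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier, ExtraTreeClassifier


@dataclass(frozen=True)
class BaseLearnerSpec:
    """One pool member: a name, its algorithm family, and a factory."""

    name: str
    family: str
    make: Callable[[int], object]  # seed -> unfitted estimator


def default_pool(seed: int = 0) -> list[BaseLearnerSpec]:
    """The default 18-member heterogeneous pool.

    Rule/table inducers without a scikit-learn counterpart (decision
    table, conjunctive rule, one-rule, RIPPER, functional trees) are
    represented by shallow/entropy decision trees and gradient boosting —
    near-equivalents within the same algorithm families. Scale-sensitive
    members (margin, logistic, nearest-neighbour) standardise their
    inputs, matching the default normalisation of the classic SMO and
    instance-based implementations.
    """

    def scaled(est):
        return make_pipeline(StandardScaler(), est)

    return [
        BaseLearnerSpec("smo", "margin classifier",
                        lambda s: scaled(LinearSVC(C=1.0, random_state=s))),
        BaseLearnerSpec("libsvm", "kernel margin classifier",
                        lambda s: scaled(SVC(kernel="rbf", C=1.0, random_state=s))),
        BaseLearnerSpec("logistic", "logistic regression",
                        lambda s: scaled(LogisticRegression(max_iter=2000, random_state=s))),
        BaseLearnerSpec("ib1", "nearest neighbour",
                        lambda s: scaled(KNeighborsClassifier(n_neighbors=1))),
        BaseLearnerSpec("ib5", "nearest neighbour",
                        lambda s: scaled(KNeighborsClassifier(n_neighbors=5))),
        BaseLearnerSpec("ib10", "nearest neighbour",
                        lambda s: scaled(KNeighborsClassifier(n_neighbors=10))),
        BaseLearnerSpec("decision_table", "decision table",
                        lambda s: DecisionTreeClassifier(max_depth=4, min_samples_leaf=5,
                                                         random_state=s)),
        BaseLearnerSpec("conjunctive_rule", "conjunctive rule",
                        lambda s: DecisionTreeClassifier(max_depth=2, criterion="entropy",
                                                         random_state=s)),
        BaseLearnerSpec("one_rule", "one-rule",
                        lambda s: DecisionTreeClassifier(max_depth=1, criterion="entropy",
                                                         random_state=s)),
        BaseLearnerSpec("cart", "CART tree",
                        lambda s: DecisionTreeClassifier(random_state=s)),
        BaseLearnerSpec("rule_inducer", "rule inducer",
                        lambda s: DecisionTreeClassifier(max_depth=6, min_samples_leaf=10,
                                                         random_state=s)),
        BaseLearnerSpec("zero_rule", "constant predictor",
                        lambda s: DummyClassifier(strategy="most_frequent")),
        BaseLearnerSpec("random_tree", "random tree",
                        lambda s: ExtraTreeClassifier(random_state=s)),
        BaseLearnerSpec("naive_bayes", "naive Bayes",
                        lambda s: GaussianNB()),
        BaseLearnerSpec("random_forest", "random forest",
                        lambda s: RandomForestClassifier(n_estimators=50, random_state=s)),
        BaseLearnerSpec("decision_stump", "decision stump",
                        lambda s: DecisionTreeClassifier(max_depth=1, random_state=s)),
        BaseLearnerSpec("j48", "C4.5 tree",
                        lambda s: DecisionTreeClassifier(criterion="entropy", random_state=s)),
        BaseLearnerSpec("functional_tree", "model tree",
                        lambda s: GradientBoostingClassifier(n_estimators=50, random_state=s)),
    ]


def build_result_matrix(
    pool: Sequence[BaseLearnerSpec],
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "out_of_fold",
    seed: int = 0,
) -> tuple[np.ndarray, list[str], list[object]]:
    """Fit the pool and compute the binary result matrix R.

    ``mode='resubstitution'`` scores each learner on the very samples it
    was fitted on; ``mode='out_of_fold'`` (default) scores 5-fold
    out-of-fold predictions instead, which stops memorising learners
    (e.g. 1-NN) from posting a perfect row. In both modes each surviving
    learner is finally fitted on the full training data.

    Returns ``(R, names, fitted_estimators)``; learners that fail to fit
    are dropped with a warning (at least 2 must survive).
    """
    if mode not in {"resubstitution", "out_of_fold"}:
        raise ValueError(f"unknown result-matrix mode {mode!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty training set")

    min_class = np.unique(y, return_counts=True)[1].min()
    n_splits = min(5, int(min_class))
    use_oof = mode == "out_of_fold" and n_splits >= 2

    rows: list[np.ndarray] = []
    names: list[str] = []
    fitted: list[object] = []
    for i, spec in enumerate(pool):
        est = spec.make(seed + i)
        try:
            if use_oof:
                cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pred = cross_val_predict(clone(est), X, y, cv=cv)
                est.fit(X, y)
            else:
                est.fit(X, y)
                pred = est.predict(X)
        except Exception as exc:  # noqa: BLE001 - any fit failure drops the learner
            warnings.warn(f"base learner {spec.name!r} failed to fit and was dropped: {exc}")
            continue
        rows.append((pred == y).astype(np.int8))
        names.append(spec.name)
        fitted.append(est)
    if len(fitted) < 2:
        raise ValueError("fewer than 2 base learners could be fitted")
    return np.vstack(rows), names, fitted


def cluster_classifiers(R: np.ndarray, K: int = 9, seed: int = 0) -> np.ndarray:
    """Cluster learners by correctness pattern: K-means on the rows of R
    (each learner a point in {0,1}^m), with K capped at the pool size."""
    R = np.asarray(R, dtype=float)
    if R.size == 0:
        raise ValueError("empty result matrix")
    k_eff = min(K, R.shape[0])
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed)
    return km.fit_predict(R)


def _committee_correct(R_sub: np.ndarray, tiebreak_row: np.ndarray) -> np.ndarray:
    """Per-sample correctness of the committee's binary majority vote.

    With two labels, each wrong member votes the other label, so the vote
    is correct iff correct members outnumber wrong ones; an exact tie
    follows the designated top-accuracy member.
    """
    n_members = R_sub.shape[0]
    n_correct = R_sub.sum(axis=0)
    correct = n_correct * 2 > n_members
    tie = n_correct * 2 == n_members
    return np.where(tie, tiebreak_row.astype(bool), correct)


def committee_accuracy(R: np.ndarray, members: Sequence[int], accuracies: np.ndarray) -> float:
    """Majority-vote accuracy of a committee over the R-samples."""
    members = list(members)
    top = members[int(np.argmax(accuracies[members]))]
    return float(_committee_correct(R[members], R[top]).mean())


def mean_pairwise_agreement(R: np.ndarray, members: Sequence[int]) -> float:
    """Mean over member pairs of the fraction of samples on which the two
    correctness flags coincide; 1.0 for a singleton committee."""
    members = list(members)
    if len(members) < 2:
        return 1.0
    total = 0.0
    count = 0
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            total += float((R[members[a]] == R[members[b]]).mean())
            count += 1
    return total / count


@dataclass
class SelectionResult:
    """Outcome of circulating forward selection."""

    chosen: list[int]                # pool indices, in order of addition
    achieved_accuracy: float
    learner_accuracy: np.ndarray     # row means of R


def cefs_select(
    clusters: np.ndarray,
    R: np.ndarray,
    target_accuracy: float = 1.0,
    step: float = 0.05,
) -> SelectionResult:
    """Grow the chosen-classifier set CC by circulating forward selection.

    Candidates are the best-accuracy learner of each cluster, sorted by
    descending accuracy (ties toward the lower pool index). CC starts with
    the top candidate; each remaining candidate is added iff committee
    vote accuracy strictly increases and mean pairwise agreement strictly
    decreases. The scan repeats with the target accuracy lowered by
    ``step`` until the committee meets the current target, a full pass
    adds nothing, or candidates run out.
    """
    R = np.asarray(R)
    clusters = np.asarray(clusters)
    if R.size == 0 or clusters.size == 0:
        raise ValueError("empty candidate list")
    acc = R.mean(axis=1)

    candidates: list[int] = []
    for c in np.unique(clusters):
        members = np.flatnonzero(clusters == c)
        candidates.append(int(members[np.argmax(acc[members])]))
    candidates.sort(key=lambda i: (-acc[i], i))

    cc = [candidates[0]]
    remaining = candidates[1:]
    cur_acc = committee_accuracy(R, cc, acc)
    cur_agree = mean_pairwise_agreement(R, cc)
    target = target_accuracy
    while True:
        added_any = False
        for cand in list(remaining):
            trial = cc + [cand]
            t_acc = committee_accuracy(R, trial, acc)
            t_agree = mean_pairwise_agreement(R, trial)
            if t_acc > cur_acc and t_agree < cur_agree:
                cc = trial
                cur_acc, cur_agree = t_acc, t_agree
                remaining.remove(cand)
                added_any = True
        if cur_acc >= target or not remaining or not added_any:
            break
        target -= step
        if target < cur_acc:
            break
    return SelectionResult(chosen=cc, achieved_accuracy=cur_acc, learner_accuracy=acc)


class SelectiveEnsembleClassifier:
    """End-to-end selective ensemble: pool -> R -> clusters -> CC -> vote.

    Parameters mirror the selection procedure: ``k_clusters`` (initial
    K-means centroid count over learner correctness patterns),
    ``target_accuracy``/``step`` (circulating-selection schedule),
    ``result_mode`` (resubstitution or out-of-fold R), and an optional
    :class:`~cytosel.sampling.ResamplingPlan` applied to the training data
    inside :meth:`fit`.
    """

    def __init__(
        self,
        pool: Optional[Sequence[BaseLearnerSpec]] = None,
        k_clusters: int = 9,
        target_accuracy: float = 1.0,
        step: float = 0.05,
        result_mode: str = "out_of_fold",
        resampling_plan=None,
        seed: int = 0,
    ):
        self.pool = list(pool) if pool is not None else default_pool(seed)
        self.k_clusters = k_clusters
        self.target_accuracy = target_accuracy
        self.step = step
        self.result_mode = result_mode
        self.resampling_plan = resampling_plan
        self.seed = seed
        self._fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SelectiveEnsembleClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.resampling_plan is not None:
            from .sampling import hybrid_resample

            rs = hybrid_resample(X, y, self.resampling_plan)
            X, y = rs.X, rs.y

        R, names, fitted = build_result_matrix(
            self.pool, X, y, mode=self.result_mode, seed=self.seed
        )
        clusters = cluster_classifiers(R, K=self.k_clusters, seed=self.seed)
        sel = cefs_select(clusters, R, self.target_accuracy, self.step)

        self.learner_names_ = names
        self.estimators_ = fitted
        self.result_matrix_ = R
        self.clusters_ = clusters
        self.learner_accuracy_ = sel.learner_accuracy
        self.chosen_ = sel.chosen
        self.chosen_names_ = [names[i] for i in sel.chosen]
        self.achieved_accuracy_ = sel.achieved_accuracy
        self.classes_ = np.unique(y)
        self._fitted = True
        return self

    def _check_fitted(self) -> None:
        if not self._fitted:
            raise RuntimeError("model is not fitted")

    def _member_votes(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        return np.vstack([self.estimators_[i].predict(X) for i in self.chosen_])

    def predict(self, X: np.ndarray) -> np.ndarray:
        labels, _ = self.predict_with_votes(X)
        return labels

    def predict_with_votes(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Majority-vote labels plus the positive-vote fraction per sample.

        The positive class is the larger of the two class labels. An exact
        split vote follows the highest-accuracy committee member.
        """
        votes = self._member_votes(X)
        pos = self.classes_.max()
        neg = self.classes_.min()
        pos_votes = (votes == pos).sum(axis=0)
        n_members = votes.shape[0]
        vote_fraction = pos_votes / n_members
        labels = np.where(pos_votes * 2 > n_members, pos, neg)
        tie = pos_votes * 2 == n_members
        if tie.any():
            member_acc = self.learner_accuracy_[self.chosen_]
            top = int(np.argmax(member_acc))
            labels = np.where(tie, votes[top], labels)
        return labels, vote_fraction

    def save(self, path, metadata: Optional[dict] = None) -> None:
        """Persist the fitted model (pool, CC, metadata) to one archive."""
        self._check_fitted()
        payload = {
            "estimators": self.estimators_,
            "learner_names": self.learner_names_,
            "chosen": self.chosen_,
            "learner_accuracy": self.learner_accuracy_,
            "achieved_accuracy": self.achieved_accuracy_,
            "classes": self.classes_,
            "params": {
                "k_clusters": self.k_clusters,
                "target_accuracy": self.target_accuracy,
                "step": self.step,
                "result_mode": self.result_mode,
                "seed": self.seed,
            },
            "metadata": metadata or {},
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "SelectiveEnsembleClassifier":
        payload = joblib.load(path)
        model = cls(pool=[], **payload["params"])
        model.estimators_ = payload["estimators"]
        model.learner_names_ = payload["learner_names"]
        model.chosen_ = payload["chosen"]
        model.chosen_names_ = [model.learner_names_[i] for i in model.chosen_]
        model.learner_accuracy_ = payload["learner_accuracy"]
        model.achieved_accuracy_ = payload["achieved_accuracy"]
        model.classes_ = payload["classes"]
        model.metadata_ = payload["metadata"]
        model._fitted = True
        return model
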