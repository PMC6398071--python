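"""Registry of wrapper/validation learners behind one train/predict contract.

All learners are deterministic given their seed.  Classification learners
additionally return a per-class score matrix (class probabilities) usable
for ROC curves.  Standard estimators come from scikit-learn; the Random
Committee — an ensemble whose members differ only in their random seed and
whose output is the straight average of member outputs — is implemented
here on top of randomised decision trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, NamedTuple

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .dataset_io import CLASSIFICATION, REGRESSION

REGISTRY: dict[str, dict[str, Any]] = {
    "linear_regression": {"tasks": {REGRESSION}},
    "regression_tree": {"tasks": {REGRESSION}},
    "decision_tree": {"tasks": {CLASSIFICATION}},
    "knn": {"tasks": {REGRESSION, CLASSIFICATION}},
    "mlp": {"tasks": {REGRESSION, CLASSIFICATION}},
    "random_forest": {"tasks": {REGRESSION, CLASSIFICATION}},
    "random_committee": {"tasks": {REGRESSION, CLASSIFICATION}},
}

PHASE2_LEARNERS = ("random_forest", "random_committee", "mlp")


class ModelZooError(ValueError):
    """Unknown learner identifier or task mismatch."""


@dataclass(frozen=True)
class LearnerSpec:
    """A learner identifier plus hyperparameters and a seed.

    Hyperparameters override the registry defaults; unknown identifiers
    raise :class:`ModelZooError` at build time.
    """

    identifier: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def with_seed(self, seed: int) -> "LearnerSpec":
        return LearnerSpec(self.identifier, dict(self.hyperparameters), seed)


class Prediction(NamedTuple):
    predictions: np.ndarray
    scores: np.ndarray | None  # (n_test, n_classes) class probabilities
    classes: list[str] | None  # column order of `scores`


def _check(spec: LearnerSpec, task: str) -> None:
    if spec.identifier not in REGISTRY:
        raise ModelZooError(
            f"unknown learner {spec.identifier!r}; known: {sorted(REGISTRY)}"
        )
    if task not in REGISTRY[spec.identifier]["tasks"]:
        raise ModelZooError(f"learner {spec.identifier!r} does not support {task}")


def _mlp_hidden(n_features: int, n_classes: int) -> int:
    # one hidden layer sized (n_features + n_classes) / 2, sigmoid units
    return max(2, int(round((n_features + n_classes) / 2)))


def _build(spec: LearnerSpec, task: str, n_features: int, n_train: int, n_classes: int):
    hp = dict(spec.hyperparameters)
    ident, seed = spec.identifier, spec.seed
    if ident == "linear_regression":
        return LinearRegression(**hp)
    if ident == "regression_tree":
        hp.setdefault("ccp_alpha", 0.0)
        return DecisionTreeRegressor(random_state=seed, **hp)
    if ident == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if ident == "knn":
        k = min(int(hp.pop("n_neighbors", 3)), n_train)
        cls = KNeighborsClassifier if task == CLASSIFICATION else KNeighborsRegressor
        # Euclidean distance is scale-sensitive: standardise on training stats
        return Pipeline(
            [("scale", StandardScaler()), ("knn", cls(n_neighbors=k, **hp))]
        )
    if ident == "mlp":
        hidden = hp.pop("hidden_layer_sizes", (_mlp_hidden(n_features, n_classes),))
        hp.setdefault("max_iter", 400)
        cls = MLPClassifier if task == CLASSIFICATION else MLPRegressor
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    cls(
                        hidden_layer_sizes=hidden,
                        activation="logistic",
                        random_state=seed,
                        **hp,
                    ),
                ),
            ]
        )
    if ident == "random_forest":
        hp.setdefault("n_estimators", 100)
        cls = RandomForestClassifier if task == CLASSIFICATION else RandomForestRegressor
        return cls(random_state=seed, **hp)
    raise ModelZooError(f"no builder for {ident!r}")


def _random_tree_spec(task: str, hp: dict[str, Any], seed: int) -> LearnerSpec:
    base_hp = {"max_features": hp.get("max_features", "sqrt")}
    ident = "decision_tree" if task == CLASSIFICATION else "regression_tree"
    return LearnerSpec(ident, base_hp, seed)


def fit_predict(
    spec: LearnerSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    task: str,
) -> Prediction:
    """Train ``spec`` on the training block and predict every test row.

    Returns predictions and, for classification, per-class probability
    scores with their class order.  Deterministic given ``spec.seed``.
    """
    _check(spec, task)
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.shape[1] != X_test.shape[1]:
        raise ModelZooError("train/test feature dimension mismatch")
    if len(y_train) != X_train.shape[0]:
        raise ModelZooError("y_train length mismatch")

    if spec.identifier == "random_committee":
        hp = dict(spec.hyperparameters)
        n_members = int(hp.pop("n_members", 10))
        base = _random_tree_spec(task, hp, spec.seed)
        return random_committee_predict(
            base, n_members, spec.seed, X_train, y_train, X_test, task
        )

    n_classes = len(set(y_train)) if task == CLASSIFICATION else 1
    est = _build(spec, task, X_train.shape[1], X_train.shape[0], n_classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X_train, np.asarray(y_train))
        preds = est.predict(X_test)
    if task == CLASSIFICATION:
        scores = est.predict_proba(X_test)
        classes = [str(c) for c in est.classes_]
        return Prediction(np.asarray(preds, dtype=object), scores, classes)
    return Prediction(np.asarray(preds, dtype=float), None, None)


def random_committee_predict(
    base_spec: LearnerSpec,
    n_members: int,
    seed: int,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    task: str,
) -> Prediction:
    """Random Committee: member ``i`` runs the base learner with seed
    ``seed + i``; the committee output is the arithmetic mean of member
    outputs (mean class-probability vectors, then argmax, for
    classification; mean prediction for regression)."""
    if n_members < 1:
        raise ModelZooError("random committee needs n_members >= 1")
    if task == CLASSIFICATION:
        classes = sorted({str(v) for v in y_train})
        acc = np.zeros((X_test.shape[0], len(classes)))
        col = {c: j for j, c in enumerate(classes)}
        for i in range(n_members):
            member = fit_predict(
                base_spec.with_seed(seed + i), X_train, y_train, X_test, task
            )
            for j, c in enumerate(member.classes):
                acc[:, col[c]] += member.scores[:, j]
        acc /= n_members
        preds = np.array([classes[j] for j in acc.argmax(axis=1)], dtype=object)
        return Prediction(preds, acc, classes)
    acc_r = np.zeros(X_test.shape[0])
    for i in range(n_members):
        member = fit_predict(
            base_spec.with_seed(seed + i), X_train, y_train, X_test, task
        )
        acc_r += member.predictions
    return Prediction(acc_r / n_members, None, None)
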