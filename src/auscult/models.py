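"""The six supervised classifiers and cost-sensitive prediction.

Configurations are fixed to the study protocol: a linear-kernel SVM with no
hyperparameter tuning (one-vs-one multi-class), a single-hidden-layer
neural network with 10 ReLU units trained by Adam, 1-nearest-neighbor,
an unrestricted Gini decision tree, a kernel-density naive Bayes
(per-feature Gaussian kernels, Silverman bandwidth), and a 100-tree
bootstrap random forest with sqrt(p) features per split.

Decisions minimize expected cost under a K x K misclassification cost
matrix; the default symmetric 0/1 matrix makes this identical to plain
argmax-posterior prediction.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .audio_io import AudioValidationError
from .features import FeatureMatrix

MODEL_KINDS = ("svm_linear", "neural_net", "knn", "decision_tree",
               "naive_bayes_kernel", "random_forest")

#: Short aliases accepted by the CLI.
KIND_ALIASES = {"svm": "svm_linear", "nn": "neural_net", "knn": "knn",
                "dt": "decision_tree", "nb": "naive_bayes_kernel",
                "rf": "random_forest"}


def default_cost_matrix(n_classes: int) -> np.ndarray:
    """Symmetric 0/1 cost: 0 for correct, 1 for any misclassification."""
    return np.ones((n_classes, n_classes)) - np.eye(n_classes)


@dataclass(frozen=True)
class ModelSpec:
    """Choice of classifier kind plus optional hyperparameter overrides."""

    kind: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    cost_matrix: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        kind = KIND_ALIASES.get(self.kind, self.kind)
        object.__setattr__(self, "kind", kind)
        if kind not in MODEL_KINDS:
            raise AudioValidationError(
                f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")


class KernelNaiveBayes:
    """Naive Bayes with per-feature Gaussian kernel density estimates.

    Class-conditional densities are products of univariate KDEs (Silverman
    bandwidth).  Zero-variance features within a class fall back to a
    narrow Gaussian centered on the constant value.
    """

    _FALLBACK_SD = 1e-6

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KernelNaiveBayes":
        self.classes_ = np.unique(y)
        self._kdes: list[list[Any]] = []
        self._priors = np.zeros(len(self.classes_))
        for ci, klass in enumerate(self.classes_):
            rows = X[y == klass]
            self._priors[ci] = len(rows) / len(X)
            feats: list[Any] = []
            for j in range(X.shape[1]):
                col = rows[:, j]
                if np.std(col) == 0:
                    feats.append(("delta", float(col[0])))
                else:
                    feats.append(("kde", gaussian_kde(col, bw_method="silverman")))
            self._kdes.append(feats)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        log_post = np.zeros((len(X), len(self.classes_)))
        for ci in range(len(self.classes_)):
            ll = np.log(self._priors[ci])
            acc = np.full(len(X), ll)
            for j, (kind, est) in enumerate(self._kdes[ci]):
                if kind == "delta":
                    dens = np.exp(-0.5 * ((X[:, j] - est) / self._FALLBACK_SD) ** 2)
                    dens /= self._FALLBACK_SD * np.sqrt(2 * np.pi)
                else:
                    dens = est.evaluate(X[:, j])
                acc += np.log(np.maximum(dens, 1e-300))
            log_post[:, ci] = acc
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.kind == "svm_linear":
        # SVC multi-class is one-vs-one by construction; probability
        # estimates are only needed for non-default cost matrices.
        needs_proba = spec.cost_matrix is not None
        return SVC(kernel="linear", probability=needs_proba,
                   random_state=spec.seed, **hp)
    if spec.kind == "neural_net":
        return MLPClassifier(
            hidden_layer_sizes=(hp.pop("hidden_units", 10),),
            activation="relu", solver="adam",
            learning_rate_init=hp.pop("learning_rate", 1e-3),
            max_iter=hp.pop("max_epochs", 500),
            tol=1e-6, n_iter_no_change=20,
            random_state=spec.seed, **hp)
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=hp.pop("k", 1),
                                    metric="euclidean", **hp)
    if spec.kind == "decision_tree":
        return DecisionTreeClassifier(
            criterion="gini", max_depth=None,
            min_samples_leaf=hp.pop("min_samples_leaf", 1),
            random_state=spec.seed, **hp)
    if spec.kind == "naive_bayes_kernel":
        return KernelNaiveBayes()
    # random_forest
    return RandomForestClassifier(
        n_estimators=hp.pop("n_trees", 100),
        max_features=hp.pop("max_features", "sqrt"),
        bootstrap=hp.pop("bootstrap", True),
        random_state=spec.seed, **hp)


@dataclass
class TrainedModel:
    """A fitted classifier bound to its training feature layout."""

    spec: ModelSpec
    estimator: Any
    feature_names: list[str]
    classes: np.ndarray

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        model = pickle.loads(Path(path).read_bytes())
        if not isinstance(model, cls):
            raise AudioValidationError(f"{path} is not a saved model bundle")
        return model


def train(spec: ModelSpec, matrix: FeatureMatrix) -> TrainedModel:
    """Fit one classifier on a feature matrix; seed-reproducible."""
    classes = np.unique(matrix.labels)
    if len(classes) < 2:
        raise AudioValidationError("training set contains a single class")
    if matrix.X.isna().any().any():
        raise AudioValidationError("training matrix contains missing values")
    estimator = _build_estimator(spec)
    estimator.fit(matrix.X.to_numpy(dtype=float), matrix.labels)
    return TrainedModel(spec=spec, estimator=estimator,
                        feature_names=list(matrix.X.columns),
                        classes=np.asarray(estimator.classes_))


def predict(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Minimum-expected-cost labels for each row of ``matrix``.

    With the default symmetric 0/1 cost matrix this reduces to the
    argmax-posterior prediction of the underlying estimator.
    """
    if list(matrix.X.columns) != model.feature_names:
        raise AudioValidationError(
            "feature columns differ from the model's training layout")
    if len(matrix) == 0:
        return np.array([], dtype=model.classes.dtype)
    X = matrix.X.to_numpy(dtype=float)
    cost = model.spec.cost_matrix
    if cost is None:
        return np.asarray(model.estimator.predict(X))
    cost = np.asarray(cost, dtype=float)
    if cost.shape != (len(model.classes),) * 2:
        raise AudioValidationError(
            f"cost matrix shape {cost.shape} does not match "
            f"{len(model.classes)} classes")
    proba = model.estimator.predict_proba(X)
    expected_cost = proba @ cost  # (n, K): expected cost of predicting k
    return model.classes[np.argmin(expected_cost, axis=1)]
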