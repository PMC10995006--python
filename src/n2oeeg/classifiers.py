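"""The three classifier families used in the analysis.

* a soft-margin linear support-vector machine (binary),
* its one-versus-one multi-class extension with majority voting,
* an exploratory PCA + Fisher linear-discriminant classifier.

Hyperparameters follow the convention of leaving everything at its
default: box constraint C=1, no kernel, no feature standardization. The
margin optimisation is delegated to libsvm via scikit-learn; the
one-versus-one voting, its tie-breaking, and the Fisher discriminant are
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.svm import SVC


def _as_matrix(X, feature_names: Sequence[str] | None):
    """Validate a feature block against the training schema."""
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in X.columns]
            extra = [c for c in X.columns if c not in feature_names]
            if missing or extra:
                raise ValueError(
                    f"feature schema mismatch: missing columns {missing}, "
                    f"unexpected columns {extra}"
                )
            X = X[list(feature_names)]
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if feature_names is not None and X.shape[1] != len(feature_names):
        raise ValueError(
            f"feature schema mismatch: expected {len(feature_names)} columns, "
            f"got {X.shape[1]}"
        )
    return X, feature_names


@dataclass
class LinearSVM:
    """Soft-margin maximum-margin linear separator (hinge loss, L2 penalty).

    Predicts ``classes[1]`` where the affine score w·x + b is positive,
    ``classes[0]`` otherwise. No feature standardization is applied.
    """

    box_constraint: float = 1.0
    weights: np.ndarray | None = None
    bias: float | None = None
    classes: Tuple | None = None
    feature_names: List[str] | None = None

    def fit(self, X, y) -> "LinearSVM":
        Xm, names = _as_matrix(X, None)
        y = np.asarray(y)
        labels = np.unique(y)
        if labels.size != 2:
            raise ValueError(f"binary SVM needs exactly 2 classes, got {labels.size}")
        svc = SVC(kernel="linear", C=self.box_constraint, tol=1e-6)
        svc.fit(Xm, y)
        self.weights = svc.coef_.ravel().copy()
        self.bias = float(svc.intercept_[0])
        self.classes = tuple(svc.classes_)
        self.feature_names = names
        return self

    def decision_function(self, X) -> np.ndarray:
        Xm, _ = _as_matrix(X, self.feature_names)
        return Xm @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        return np.where(score > 0, self.classes[1], self.classes[0])

    def to_dict(self) -> Dict:
        return {
            "kind": "linear-svm",
            "box_constraint": self.box_constraint,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "classes": [_json_label(c) for c in self.classes],
            "feature_names": self.feature_names,
        }


@dataclass
class OvOSVM:
    """One-versus-one multi-class scheme over pairwise linear SVMs.

    One LinearSVM per unordered class pair (k(k-1)/2 models), each trained
    only on that pair's rows. Prediction is by vote count; ties are broken
    by the larger sum of |decision function| over the pairwise models that
    voted for the tied class, then by the smallest class label.
    """

    box_constraint: float = 1.0
    classes: Tuple | None = None
    pair_models: Dict[Tuple, LinearSVM] = field(default_factory=dict)
    feature_names: List[str] | None = None

    def fit(self, X, y) -> "OvOSVM":
        y = np.asarray(y)
        labels = np.unique(y)
        if labels.size < 2:
            raise ValueError("one-versus-one needs at least 2 classes")
        Xm, names = _as_matrix(X, None)
        self.classes = tuple(labels)
        self.feature_names = names
        self.pair_models = {}
        for a, b in combinations(labels, 2):
            mask = (y == a) | (y == b)
            if not (np.any(y == a) and np.any(y == b)):
                raise ValueError(f"empty class in pair ({a}, {b})")
            model = LinearSVM(self.box_constraint).fit(Xm[mask], y[mask])
            model.feature_names = names
            self.pair_models[(a, b)] = model
        return self

    def predict(self, X) -> np.ndarray:
        Xm, _ = _as_matrix(X, self.feature_names)
        n = Xm.shape[0]
        k = len(self.classes)
        index = {c: i for i, c in enumerate(self.classes)}
        votes = np.zeros((n, k))
        strength = np.zeros((n, k))  # summed |score| of winning votes
        for (a, b), model in self.pair_models.items():
            score = Xm @ model.weights + model.bias
            pred_b = score > 0
            winner = np.where(pred_b, index[b], index[a])
            votes[np.arange(n), winner] += 1
            strength[np.arange(n), winner] += np.abs(score)
        out = []
        for i in range(n):
            best = np.flatnonzero(votes[i] == votes[i].max())
            if best.size > 1:
                tied = best[strength[i, best] == strength[i, best].max()]
                best = tied
            # smallest class label among any remaining tie
            out.append(self.classes[best.min()])
        return np.asarray(out)

    def to_dict(self) -> Dict:
        return {
            "kind": "ovo-svm",
            "box_constraint": self.box_constraint,
            "classes": [_json_label(c) for c in self.classes],
            "pairs": {
                f"{a}|{b}": m.to_dict() for (a, b), m in self.pair_models.items()
            },
        }


@dataclass
class PCALDAClassifier:
    """PCA dimensionality reduction followed by a Fisher linear discriminant.

    Components are fitted on centered training features only (training-fold
    mean; no leakage into test projection). The Fisher discriminant on the
    retained scores uses pooled within-class scatter with a small ridge
    (1e-8 x trace) for singular scatter matrices; the decision threshold is
    the score of the midpoint between the projected class means under the
    pooled-scatter metric.
    """

    n_components: int = 2
    mean_: np.ndarray | None = None
    components_: np.ndarray | None = None
    explained_variance_ratio_: np.ndarray | None = None
    direction_: np.ndarray | None = None
    threshold_: float | None = None
    classes: Tuple | None = None
    feature_names: List[str] | None = None

    def fit(self, X, y) -> "PCALDAClassifier":
        Xm, names = _as_matrix(X, None)
        y = np.asarray(y)
        labels = np.unique(y)
        if labels.size != 2:
            raise ValueError("PCA+LDA classifier handles exactly 2 classes")
        n, p = Xm.shape
        rank = np.linalg.matrix_rank(Xm - Xm.mean(axis=0))
        if not 1 <= self.n_components <= min(n - 1, p):
            raise ValueError(
                f"n_components must be in [1, {min(n - 1, p)}] for {n} rows x {p} columns"
            )
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds feature rank {rank}"
            )
        pca = PCA(n_components=None, svd_solver="full").fit(Xm)
        self.mean_ = pca.mean_
        self.components_ = pca.components_[: self.n_components]
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.feature_names = names
        self.classes = tuple(labels)

        Z = (Xm - self.mean_) @ self.components_.T
        m0 = Z[y == labels[0]].mean(axis=0)
        m1 = Z[y == labels[1]].mean(axis=0)
        Sw = np.zeros((self.n_components, self.n_components))
        for lab, m in ((labels[0], m0), (labels[1], m1)):
            D = Z[y == lab] - m
            Sw += D.T @ D
        trace = np.trace(Sw)
        ridge = 1e-8 * (trace if trace > 0 else 1.0)
        self.direction_ = np.linalg.solve(Sw + ridge * np.eye(self.n_components), m1 - m0)
        self.threshold_ = float(self.direction_ @ (m0 + m1) / 2.0)
        return self

    def scores(self, X) -> np.ndarray:
        Xm, _ = _as_matrix(X, self.feature_names)
        return (Xm - self.mean_) @ self.components_.T

    def predict(self, X) -> np.ndarray:
        s = self.scores(X) @ self.direction_
        return np.where(s > self.threshold_, self.classes[1], self.classes[0])

    def cumulative_explained_variance(self) -> float:
        """Fraction of training variance carried by the retained components."""
        return float(self.explained_variance_ratio_[: self.n_components].sum())

    def to_dict(self) -> Dict:
        return {
            "kind": "pca-lda",
            "n_components": self.n_components,
            "mean": self.mean_.tolist(),
            "components": self.components_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "direction": self.direction_.tolist(),
            "threshold": self.threshold_,
            "classes": [_json_label(c) for c in self.classes],
            "feature_names": self.feature_names,
        }


def _json_label(c):
    return c.item() if isinstance(c, np.generic) else c


@dataclass(frozen=True)
class ModelSpec:
    """Which classifier to run: binary-svm, ovo-svm, or pca-lda(k)."""

    kind: str
    n_components: int | None = None
    box_constraint: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("binary-svm", "ovo-svm", "pca-lda"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "pca-lda" and not self.n_components:
            raise ValueError("pca-lda needs n_components")

    def make(self):
        if self.kind == "binary-svm":
            return LinearSVM(self.box_constraint)
        if self.kind == "ovo-svm":
            return OvOSVM(self.box_constraint)
        return PCALDAClassifier(self.n_components)


def train_linear_svm(features, labels, box_constraint: float = 1.0) -> LinearSVM:
    """Fit a binary soft-margin linear SVM (C = box_constraint, default 1)."""
    return LinearSVM(box_constraint).fit(features, labels)


def train_ovo_multiclass(features, labels, box_constraint: float = 1.0) -> OvOSVM:
    """Fit a one-versus-one multi-class linear SVM."""
    return OvOSVM(box_constraint).fit(features, labels)


def train_pca_lda(features, labels, n_components: int) -> PCALDAClassifier:
    """Fit PCA (training-set centering) + Fisher LDA on retained scores."""
    return PCALDAClassifier(n_components).fit(features, labels)
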