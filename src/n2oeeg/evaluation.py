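"""Leave-one-participant-out evaluation and the shuffle-test baseline.

Cross-validation folds hold out every observation of one participant, so
accuracy measures generalisation across people. The empirical chance
baseline re-runs the identical procedure with training labels permuted
(within each fold's training set, independently per iteration and fold);
test labels are never touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from ._seeds import substream
from .classifiers import ModelSpec, PCALDAClassifier
from .spectra import feature_columns

FoldPartition = List[Tuple[Tuple[str, ...], str]]


def lopo_partition(feature_table: pd.DataFrame) -> FoldPartition:
    """One fold per participant, ordered by sorted participant id.

    Each fold is (train participant ids, test participant id); every
    participant is the test participant exactly once.
    """
    ids = sorted(feature_table["participant_id"].astype(str).unique())
    if len(ids) < 2:
        raise ValueError("leave-one-participant-out needs at least 2 participants")
    return [(tuple(p for p in ids if p != test), test) for test in ids]


@dataclass
class CVResult:
    """Per-fold confusion matrices and accuracies from one CV run."""

    model: str
    labels: Tuple[int, ...]
    fold_participants: List[str]
    confusions: List[np.ndarray]  # true x predicted counts per fold
    accuracies: np.ndarray

    @property
    def n_folds(self) -> int:
        return len(self.fold_participants)

    @property
    def aggregate_confusion(self) -> pd.DataFrame:
        total = np.sum(self.confusions, axis=0)
        return pd.DataFrame(total, index=list(self.labels), columns=list(self.labels))

    @property
    def pooled_counts(self) -> Tuple[int, int]:
        """(correct, total) pooled over folds."""
        total = np.sum(self.confusions, axis=0)
        return int(np.trace(total)), int(total.sum())

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    def to_dict(self) -> Dict:
        return {
            "model": self.model,
            "labels": [int(l) for l in self.labels],
            "fold_participants": self.fold_participants,
            "fold_accuracies": self.accuracies.tolist(),
            "confusions": [c.tolist() for c in self.confusions],
            "mean_accuracy": self.mean_accuracy,
        }


def _split(table: pd.DataFrame, fold):
    train_ids, test_id = fold
    pid = table["participant_id"].astype(str)
    train = table[pid.isin(train_ids)]
    test = table[pid == test_id]
    return train, test


def _fit_predict(train: pd.DataFrame, test: pd.DataFrame, spec: ModelSpec, fold_id: str):
    cols = feature_columns(train)
    y_train = train["condition_pct"].to_numpy()
    if spec.kind in ("binary-svm", "pca-lda") and np.unique(y_train).size != 2:
        raise ValueError(
            f"fold {fold_id!r}: {spec.kind} needs exactly 2 training classes, "
            f"got {sorted(np.unique(y_train))}"
        )
    model = spec.make().fit(train[cols], y_train)
    return model.predict(test[cols])


def _confusion(y_true, y_pred, labels) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    out = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        out[index[t], index[p]] += 1
    return out


def run_cv(
    feature_table: pd.DataFrame,
    model_spec: ModelSpec,
    partition: FoldPartition | None = None,
) -> CVResult:
    """Train on each fold's training participants, test on the held-out one.

    Nothing from the test participant enters training — including PCA
    centering, which uses training-fold means only.
    """
    if partition is None:
        partition = lopo_partition(feature_table)
    labels = tuple(int(v) for v in sorted(feature_table["condition_pct"].unique()))
    confusions, accuracies, fold_ids = [], [], []
    for fold in partition:
        train, test = _split(feature_table, fold)
        if train.empty or test.empty:
            raise ValueError(f"fold {fold[1]!r} has an empty train or test set")
        y_pred = _fit_predict(train, test, model_spec, fold[1])
        y_true = test["condition_pct"].to_numpy()
        cm = _confusion(y_true, y_pred, labels)
        confusions.append(cm)
        accuracies.append(np.trace(cm) / cm.sum())
        fold_ids.append(fold[1])
    return CVResult(
        model=_describe(model_spec),
        labels=labels,
        fold_participants=fold_ids,
        confusions=confusions,
        accuracies=np.asarray(accuracies, dtype=float),
    )


def _describe(spec: ModelSpec) -> str:
    if spec.kind == "pca-lda":
        return f"pca-lda({spec.n_components})"
    return spec.kind


def pooled_accuracy_ci(
    cv_result: CVResult, alpha: float = 0.05
) -> Tuple[float, float, float]:
    """Mean fold accuracy with an exact (Clopper-Pearson) binomial CI.

    The CI is computed on the pooled correct/total counts; with equal fold
    sizes the mean of fold accuracies equals the pooled proportion.
    """
    if cv_result.n_folds < 1:
        raise ValueError("no folds in CV result")
    correct, total = cv_result.pooled_counts
    if total == 0:
        raise ValueError("empty folds")
    ci = binomtest(correct, total).proportion_ci(confidence_level=1 - alpha, method="exact")
    return cv_result.mean_accuracy, float(ci.low), float(ci.high)


@dataclass
class BaselineResult:
    """Shuffle-test chance distribution for one model/partition."""

    model: str
    n_iterations: int
    per_iteration: np.ndarray  # overall accuracy per iteration
    per_fold_mean: np.ndarray  # mean over iterations, per fold
    fold_participants: List[str] = field(default_factory=list)

    @property
    def grand_mean(self) -> float:
        return float(self.per_iteration.mean())

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.per_iteration, q))

    def to_dict(self) -> Dict:
        return {
            "model": self.model,
            "n_iterations": self.n_iterations,
            "per_iteration_accuracy": self.per_iteration.tolist(),
            "per_fold_mean_accuracy": self.per_fold_mean.tolist(),
            "fold_participants": self.fold_participants,
            "grand_mean": self.grand_mean,
        }


def shuffle_baseline(
    feature_table: pd.DataFrame,
    model_spec: ModelSpec,
    partition: FoldPartition | None = None,
    n_iterations: int = 100,
    seed: int = 0,
) -> BaselineResult:
    """Empirical chance level: CV with training labels permuted.

    On each iteration, every fold's training labels are permuted uniformly
    at random (a dedicated substream per (iteration, fold)); the model is
    retrained and scored on the untouched test labels. The grand mean over
    iterations estimates chance-level accuracy.
    """
    if n_iterations < 1:
        raise ValueError("need at least 1 shuffle iteration")
    if partition is None:
        partition = lopo_partition(feature_table)
    labels = tuple(int(v) for v in sorted(feature_table["condition_pct"].unique()))
    n_folds = len(partition)
    fold_acc = np.empty((n_iterations, n_folds))
    for it in range(n_iterations):
        for f, fold in enumerate(partition):
            train, test = _split(feature_table, fold)
            rng = substream(seed, "shuffle", it, f)
            shuffled = train.copy()
            shuffled["condition_pct"] = rng.permutation(train["condition_pct"].to_numpy())
            # A permutation can leave a fold single-classed only if the fold
            # itself is; the design is balanced so this cannot occur.
            y_pred = _fit_predict(shuffled, test, model_spec, fold[1])
            fold_acc[it, f] = np.mean(y_pred == test["condition_pct"].to_numpy())
    return BaselineResult(
        model=_describe(model_spec),
        n_iterations=n_iterations,
        per_iteration=fold_acc.mean(axis=1),
        per_fold_mean=fold_acc.mean(axis=0),
        fold_participants=[fold[1] for fold in partition],
    )


def pca_lda_curve(
    feature_table: pd.DataFrame,
    partition: FoldPartition | None = None,
    max_components: int = 20,
) -> pd.DataFrame:
    """CV accuracy and cumulative explained variance vs component count.

    For k = 1..max_components, runs leave-one-participant-out CV with the
    PCA+LDA classifier retaining k components, and reports the cumulative
    explained variance of the training-fold PCA averaged over folds. The
    curve is truncated (with a warning) at the achievable training rank.
    """
    if partition is None:
        partition = lopo_partition(feature_table)
    cols = feature_columns(feature_table)
    min_rank = min(
        np.linalg.matrix_rank(
            _split(feature_table, fold)[0][cols].to_numpy()
            - _split(feature_table, fold)[0][cols].to_numpy().mean(axis=0)
        )
        for fold in partition
    )
    if max_components > min_rank:
        warnings.warn(
            f"max_components {max_components} exceeds training rank {min_rank}; "
            "curve truncated"
        )
        max_components = int(min_rank)
    rows = []
    for k in range(1, max_components + 1):
        cv = run_cv(feature_table, ModelSpec("pca-lda", n_components=k), partition)
        cumvar = []
        for fold in partition:
            train, _ = _split(feature_table, fold)
            model = PCALDAClassifier(k).fit(train[cols], train["condition_pct"].to_numpy())
            cumvar.append(model.cumulative_explained_variance())
        rows.append(
            {
                "n_components": k,
                "cv_accuracy": cv.mean_accuracy,
                "cumulative_explained_variance": float(np.mean(cumvar)),
            }
        )
    return pd.DataFrame(rows)
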