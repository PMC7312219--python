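"""Wrapper fitness oracle: score a channel subset by cross-validated
classification accuracy over a four-classifier portfolio.

For every subset the portfolio (SVM with sigmoid/linear/RBF kernels,
k-NN with 1-9 neighbours, random forest with depths 2-5, Gaussian naive
Bayes) is evaluated on the same stratified folds; each family's best
parameter setting is kept and the returned accuracy is the maximum over
families.  This parameter choice is made on the evaluation folds
themselves — optimistically biased, but it is the selection rule the
wrapper search is built around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureTable

__all__ = [
    "PortfolioSpec",
    "SubsetScore",
    "stratified_folds",
    "confusion_metrics",
    "evaluate_subset",
]

#: deterministic tie-break order between classifier families
FAMILY_PRIORITY = ("svm", "knn", "rf", "nb")


@dataclass(frozen=True)
class PortfolioSpec:
    """Classifier families and parameter grids to race per subset."""

    svm_kernels: tuple[str, ...] = ("sigmoid", "linear", "rbf")
    knn_neighbors: tuple[int, ...] = tuple(range(1, 10))
    rf_depths: tuple[int, ...] = (2, 3, 4, 5)
    include_nb: bool = True
    svm_c: float = 1.0
    rf_n_estimators: int = 100

    def __post_init__(self) -> None:
        if not (self.svm_kernels or self.knn_neighbors or self.rf_depths or self.include_nb):
            raise ValueError("at least one classifier family must be enabled")

    def candidates(self, seed: int):
        """Yield (family, param_desc, estimator factory) triples."""
        for kern in self.svm_kernels:
            yield "svm", f"kernel={kern}", lambda k=kern: SVC(kernel=k, C=self.svm_c, gamma="scale")
        for n in self.knn_neighbors:
            yield "knn", f"n_neighbors={n}", lambda n=n: KNeighborsClassifier(n_neighbors=n)
        for d in self.rf_depths:
            yield "rf", f"max_depth={d}", lambda d=d: RandomForestClassifier(
                n_estimators=self.rf_n_estimators, max_depth=d, random_state=seed
            )
        if self.include_nb:
            yield "nb", "gaussian", lambda: GaussianNB()


@dataclass
class SubsetScore:
    """CV result for one channel subset."""

    accuracy: float
    classifier_id: str
    sensitivity: float | None
    specificity: float | None
    per_family_accuracies: dict[str, float] = field(default_factory=dict)
    n_folds: int = 0


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified partition of instance indices into test folds.

    If the minority class has fewer than ``k`` members, ``k`` is reduced
    to that count (e.g. 9-fold when only 9 positives exist).
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError("each class needs at least 2 members")
    k = min(k, min_count)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float | None, float | None]:
    """(accuracy, sensitivity, specificity) with seizure (1) as positive.

    A rate whose denominator class is absent from ``y_true`` is returned
    as None rather than 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = (tp + tn) / y_true.size
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return acc, sens, spec


def _cv_run(X: np.ndarray, y: np.ndarray, folds: list[np.ndarray], make_est) -> tuple[float, np.ndarray]:
    """Mean fold accuracy and pooled out-of-fold predictions.

    Standardization is fit on the training folds only.
    """
    n = y.size
    pooled = np.empty(n, dtype=int)
    fold_accs = []
    all_idx = np.arange(n)
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        pipe = Pipeline([("scale", StandardScaler()), ("clf", make_est())])
        pipe.fit(X[train_idx], y[train_idx])
        pred = pipe.predict(X[test_idx])
        pooled[test_idx] = pred
        fold_accs.append(float(np.mean(pred == y[test_idx])))
    return float(np.mean(fold_accs)), pooled


def evaluate_subset(
    table: FeatureTable,
    subset,
    portfolio: PortfolioSpec = PortfolioSpec(),
    k: int = 10,
    seed: int = 0,
) -> SubsetScore:
    """Best cross-validated accuracy of a channel subset over the
    classifier portfolio.

    All candidates are scored on the same seeded stratified folds; the
    winner's pooled out-of-fold predictions supply sensitivity and
    specificity.  Family ties resolve by ``FAMILY_PRIORITY``; ties within
    a family by grid order.  Deterministic given ``seed``.
    """
    subset = sorted(set(subset))
    if not subset:
        raise ValueError("subset must be nonempty")
    if any(ch < 0 or ch >= table.n_channels for ch in subset):
        raise ValueError(f"subset {subset} not within montage of {table.n_channels} channels")
    X = table.matrix[:, table.subset_columns(subset)]
    y = table.labels
    folds = stratified_folds(y, k, seed)

    best: dict[str, tuple[float, str, np.ndarray]] = {}
    for family, desc, make_est in portfolio.candidates(seed):
        acc, pooled = _cv_run(X, y, folds, make_est)
        if family not in best or acc > best[family][0]:
            best[family] = (acc, desc, pooled)

    win_family = max(
        best, key=lambda f: (best[f][0], -FAMILY_PRIORITY.index(f))
    )
    win_acc, win_desc, win_pooled = best[win_family]
    _, sens, spec = confusion_metrics(y, win_pooled)
    return SubsetScore(
        accuracy=win_acc,
        classifier_id=f"{win_family}({win_desc})",
        sensitivity=sens,
        specificity=spec,
        per_family_accuracies={f: best[f][0] for f in best},
        n_folds=len(folds),
    )
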