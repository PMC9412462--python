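"""Binary motion-sickness classification with permutation validation.

Four classifiers at fixed hyperparameters — LDA (pooled-covariance linear
discriminant), KNN with 28 Euclidean neighbors, a deviance-reduction decision
tree limited to 2 splits, and a linear SVM with box constraint 0.0706 —
evaluated by stratified 10-fold cross-validation with fold-internal
standardization. Metrics: accuracy, recall, precision, F1, ROC/AUC. The
permutation test re-runs the full cross-validation on label-shuffled data and
reports an add-one p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from vimshrv.hrv_features import FeatureVector
from vimshrv.synthetic_data import CohortDataset

__all__ = [
    "ClassifierSpec",
    "ClassifierReport",
    "PermutationResult",
    "TrainedClassifier",
    "standardize_fit_apply",
    "fit_predict",
    "train",
    "cross_validate",
    "permutation_test",
    "classify_cohort",
    "f1_from_precision_recall",
    "CLASSIFICATION_FEATURES",
]

CLASSIFICATION_FEATURES = FeatureVector.CLASSIFICATION_FEATURES
KINDS = ("LDA", "KNN", "DT", "LSVM")


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the four classifiers at its fixed hyperparameters."""

    kind: str
    n_neighbors: int = 28  # KNN
    max_splits: int = 2  # DT
    box_constraint: float = 0.0706  # LSVM soft-margin penalty C
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "KNN" and self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.kind == "DT" and self.max_splits < 1:
            raise ValueError("max_splits must be >= 1")
        if self.kind == "LSVM" and not self.box_constraint > 0:
            raise ValueError("box_constraint must be positive")

    @classmethod
    def lda(cls) -> "ClassifierSpec":
        return cls(kind="LDA")

    @classmethod
    def knn(cls, n_neighbors: int = 28) -> "ClassifierSpec":
        return cls(kind="KNN", n_neighbors=n_neighbors)

    @classmethod
    def dt(cls, max_splits: int = 2) -> "ClassifierSpec":
        return cls(kind="DT", max_splits=max_splits)

    @classmethod
    def lsvm(cls, box_constraint: float = 0.0706) -> "ClassifierSpec":
        return cls(kind="LSVM", box_constraint=box_constraint)

    @classmethod
    def all_four(cls) -> tuple["ClassifierSpec", ...]:
        return (cls.lda(), cls.knn(), cls.dt(), cls.lsvm())


@dataclass(frozen=True)
class ClassifierReport:
    """Pooled out-of-fold cross-validation metrics (percentages except AUC)."""

    accuracy: float
    recall: float
    precision: float
    f1: float
    auc: float
    roc_points: np.ndarray  # (n, 2) columns fpr, tpr
    confusion: np.ndarray  # [[tn, fp], [fn, tp]]
    fold_assignments: np.ndarray


@dataclass(frozen=True)
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    n_perm: int
    p_value: float


def standardize_fit_apply(
    train_features: np.ndarray, test_features: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Z-score both sets using mean/SD estimated on the training rows only.

    Raises on a constant training feature (undefined scale).
    """
    train_features = np.asarray(train_features, dtype=float)
    test_features = np.asarray(test_features, dtype=float)
    if train_features.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    mean = train_features.mean(axis=0)
    sd = train_features.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant training feature(s) at column(s) {bad.tolist()}")
    return (train_features - mean) / sd, (test_features - mean) / sd, (mean, sd)


class _KNN:
    """Euclidean k-nearest-neighbors; 50/50 vote ties go to the single nearest neighbor."""

    def __init__(self, k: int) -> None:
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_KNN":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y, dtype=int)
        return self

    def _neighbor_labels(self, X: np.ndarray) -> np.ndarray:
        d = cdist(np.asarray(X, dtype=float), self._X)
        order = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        return self._y[order]

    def predict_scores(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nl = self._neighbor_labels(X)
        scores = nl.mean(axis=1)  # fraction of positive neighbors
        labels = (scores > 0.5).astype(int)
        ties = scores == 0.5
        if np.any(ties):
            labels[ties] = nl[ties, 0]  # nearest neighbor breaks the tie
        return labels, scores


def _build_estimator(spec: ClassifierSpec):
    if spec.kind == "LDA":
        return LinearDiscriminantAnalysis(solver="svd")
    if spec.kind == "KNN":
        return _KNN(spec.n_neighbors)
    if spec.kind == "DT":
        # "max splits = 2" caps the binary tree at 3 leaves; log-loss impurity
        # is the deviance-reduction split criterion
        return DecisionTreeClassifier(
            criterion="log_loss", max_leaf_nodes=spec.max_splits + 1, random_state=0
        )
    if spec.kind == "LSVM":
        return SVC(kernel="linear", C=spec.box_constraint)
    raise AssertionError(spec.kind)


def fit_predict(
    spec: ClassifierSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one classifier and predict labels + continuous scores on test rows.

    Scores: LDA and LSVM use the signed decision function, KNN the fraction
    of positive neighbors, DT the positive-class leaf proportion.
    """
    train_y = np.asarray(train_y, dtype=int)
    if set(np.unique(train_y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if spec.kind == "KNN" and train_X.shape[0] < spec.n_neighbors:
        raise ValueError(
            f"KNN with k = {spec.n_neighbors} requires n_train >= {spec.n_neighbors}, "
            f"got {train_X.shape[0]}"
        )
    if spec.standardize:
        train_X, test_X, _ = standardize_fit_apply(train_X, test_X)
    est = _build_estimator(spec)
    if isinstance(est, _KNN):
        est.fit(train_X, train_y)
        return est.predict_scores(test_X)
    est.fit(train_X, train_y)
    labels = est.predict(test_X).astype(int)
    if hasattr(est, "decision_function"):
        scores = est.decision_function(test_X)
    else:
        scores = est.predict_proba(test_X)[:, 1]
    return labels, np.asarray(scores, dtype=float)


@dataclass
class TrainedClassifier:
    """A classifier fitted once on a full training set, for streaming use."""

    spec: ClassifierSpec
    _train_X: np.ndarray = field(repr=False)
    _train_y: np.ndarray = field(repr=False)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return fit_predict(self.spec, self._train_X, self._train_y, np.atleast_2d(X))


def train(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> TrainedClassifier:
    """Bind a spec to its training data (fitting happens per predict call)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    fit_predict(spec, X, y, X[:1])  # validate spec/data compatibility eagerly
    return TrainedClassifier(spec=spec, _train_X=X, _train_y=y)


def _metrics_from_confusion(confusion: np.ndarray) -> tuple[float, float, float, float]:
    (tn, fp), (fn, tp) = confusion
    n = confusion.sum()
    accuracy = 100.0 * (tp + tn) / n
    recall = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else 0.0
    precision = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = f1_from_precision_recall(precision, recall) if (precision + recall) > 0 else 0.0
    return accuracy, recall, precision, f1


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); accepts and returns percentages."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        raise ValueError("precision + recall must be positive")
    return 2.0 * precision * recall / (precision + recall)


def cross_validate(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> ClassifierReport:
    """Stratified k-fold cross-validation with fold-internal standardization.

    Out-of-fold predictions and scores are pooled into a single confusion
    matrix, metric set, and ROC curve (threshold sweep, trapezoidal AUC).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    if X.shape[0] < k:
        raise ValueError(f"need at least k = {k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty(y.size, dtype=int)
    scores = np.empty(y.size, dtype=float)
    folds = np.empty(y.size, dtype=int)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold}: a class is absent from the training split")
        pred[te], scores[te] = fit_predict(spec, X[tr], y[tr], X[te])
        folds[te] = fold
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    confusion = np.array([[tn, fp], [fn, tp]])
    accuracy, recall, precision, f1 = _metrics_from_confusion(confusion)
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ClassifierReport(
        accuracy=accuracy,
        recall=recall,
        precision=precision,
        f1=f1,
        auc=auc,
        roc_points=np.column_stack([fpr, tpr]),
        confusion=confusion,
        fold_assignments=folds,
    )


def permutation_test(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10000,
    k: int = 10,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation null distribution of the cross-validated accuracy.

    ``p = (1 + #{null >= observed}) / (1 + n_perm)`` — never below
    ``1/(n_perm + 1)``. Fully reproducible from the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=int)
    observed = cross_validate(spec, X, y, k=k, seed=seed).accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        null[b] = cross_validate(spec, X, y_perm, k=k, seed=seed).accuracy
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return PermutationResult(
        observed_accuracy=observed, null_accuracies=null, n_perm=n_perm, p_value=p
    )


def cohort_feature_matrix(
    cohort: CohortDataset, positive_condition: str = "VR"
) -> tuple[np.ndarray, np.ndarray]:
    """Post-viewing feature matrix (5 columns) and binary condition labels.

    Rows are the post-viewing cells of both conditions; the positive class
    (default VR, the motion-sickness condition) is coded 1. Heart rate is
    excluded: only the five statistically informative features enter.
    """
    table = cohort.table
    post = table[table["phase"] == "post"].copy()
    missing = set(CLASSIFICATION_FEATURES) - set(post.columns)
    if missing:
        raise ValueError(f"cohort table missing feature columns: {sorted(missing)}")
    if post[list(CLASSIFICATION_FEATURES)].isna().any().any():
        raise ValueError("cohort features incomplete; extract features first")
    X = post[list(CLASSIFICATION_FEATURES)].to_numpy(dtype=float)
    y = (post["condition"] == positive_condition).to_numpy(dtype=int)
    return X, y


def classify_cohort(
    cohort: CohortDataset,
    specs: tuple[ClassifierSpec, ...] | None = None,
    n_perm: int = 10000,
    k: int = 10,
    seed: int = 0,
    positive_condition: str = "VR",
) -> dict[str, dict[str, object]]:
    """Cross-validate + permutation-test every classifier on the cohort.

    Returns a summary-table-shaped mapping ``kind -> {"report":
    ClassifierReport, "permutation": PermutationResult}``.
    """
    X, y = cohort_feature_matrix(cohort, positive_condition)
    specs = specs or ClassifierSpec.all_four()
    out: dict[str, dict[str, object]] = {}
    for spec in specs:
        report = cross_validate(spec, X, y, k=k, seed=seed)
        perm = permutation_test(spec, X, y, n_perm=n_perm, k=k, seed=seed)
        out[spec.kind] = {"report": report, "permutation": perm}
    return out
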