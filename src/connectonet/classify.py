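"""Group discrimination from connectivity features.

Subjects are represented by the vectorised upper triangle of their
Fisher-z connectivity matrix.  Classification follows the libsvm
work-flow common in neuroimaging: a two-sample-t feature screen, an SVM
over a kernel/C grid, and leave-one-subject-out cross-validation
(LOOCV), with the feature screen nested *inside* every fold so no
information from the held-out subject leaks into training.  Significance
of the observed accuracy comes from label-permutation testing, and
single network metrics (e.g. node degree) are screened with ROC/AUC and
a Fisher linear-discriminant separation score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

from .connectivity import ConnectivityMatrix, to_fisher_z, triu_index
from .errors import (
    EmptyClassError,
    InsufficientSubjectsError,
    NotSymmetricError,
    SingleClassError,
)

__all__ = [
    "FeatureMatrix",
    "ClassificationResult",
    "ROCCurveResult",
    "vectorize_edges",
    "devectorize_edges",
    "features_from_matrices",
    "select_features",
    "loocv_svm",
    "permutation_test_accuracy",
    "metric_roc",
    "lda_screen",
]

DEFAULT_KERNELS = ("linear", "polynomial", "rbf")
DEFAULT_C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0)
_KERNEL_ORDER = {"linear": 0, "polynomial": 1, "rbf": 2}
_SKLEARN_KERNEL = {"linear": "linear", "polynomial": "poly", "rbf": "rbf"}


@dataclass
class FeatureMatrix:
    """Subjects x features with binary labels.

    For whole-connectome classification the features are the vectorised
    upper-triangle Fisher-z edges and ``feature_index`` maps columns
    back to region pairs.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_index: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape[0] != self.labels.size:
            raise ValueError("one label per subject required")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")


@dataclass
class ClassificationResult:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    best_kernel: str
    best_C: float
    per_fold_predictions: np.ndarray
    decision_values: np.ndarray
    grid: dict[tuple[str, float], float] = field(default_factory=dict)
    permutation_p: float | None = None


@dataclass
class ROCCurveResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    direction: str  # "class1_higher" or "class0_higher"


def vectorize_edges(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Upper triangle (i < j), row-major, of a symmetric matrix."""
    values = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise NotSymmetricError("expected a square matrix")
    if not np.allclose(values, values.T, atol=1e-10):
        raise NotSymmetricError("matrix is not symmetric")
    i, j = triu_index(values.shape[0])
    return values[i, j].copy()


def devectorize_edges(v: np.ndarray, n_rois: int, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_edges` (diagonal filled with a constant)."""
    out = np.full((n_rois, n_rois), diagonal, dtype=float)
    i, j = triu_index(n_rois)
    out[i, j] = v
    out[j, i] = v
    return out


def features_from_matrices(
    group0: list[ConnectivityMatrix], group1: list[ConnectivityMatrix]
) -> FeatureMatrix:
    """FeatureMatrix of Fisher-z edges: group0 labelled 0, group1 labelled 1."""
    mats = [to_fisher_z(m) for m in [*group0, *group1]]
    values = np.vstack([m.upper_triangle() for m in mats])
    labels = np.array([0] * len(group0) + [1] * len(group1))
    i, j = triu_index(mats[0].n_rois)
    return FeatureMatrix(values, labels, list(zip(i.tolist(), j.tolist())))


def _edge_t_pvalues(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    x = values[labels == 1]
    y = values[labels == 0]
    res = sps.ttest_ind(x, y, axis=0, equal_var=True)
    return np.nan_to_num(res.pvalue, nan=1.0)


def select_features(
    train: FeatureMatrix, p_threshold: float
) -> np.ndarray:
    """Columns whose two-sample t-test beats p_threshold on the training set."""
    labels = train.labels
    if len(set(labels.tolist())) < 2:
        raise SingleClassError("feature selection needs both classes")
    p = _edge_t_pvalues(train.values, labels)
    return np.nonzero(p < p_threshold)[0]


def _select_or_fallback(
    values: np.ndarray, labels: np.ndarray, p_threshold: float
) -> np.ndarray:
    """Fold-level screen; falls back to the single smallest-p feature when
    nothing survives, so every fold's fit stays well-defined."""
    fm = FeatureMatrix(values, labels)
    sel = select_features(fm, p_threshold)
    if sel.size == 0:
        sel = np.array([int(np.argmin(_edge_t_pvalues(values, labels)))])
    return sel


def _loocv_single(
    values: np.ndarray,
    labels: np.ndarray,
    kernel: str,
    c: float,
    p_threshold: float,
    leaky_selection: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """One LOOCV sweep for a fixed (kernel, C); returns (preds, decisions)."""
    n = labels.size
    preds = np.zeros(n, dtype=int)
    decisions = np.zeros(n)
    for hold in range(n):
        train_idx = np.delete(np.arange(n), hold)
        x_tr, y_tr = values[train_idx], labels[train_idx]
        if leaky_selection is not None:
            sel = leaky_selection
        else:
            sel = _select_or_fallback(x_tr, y_tr, p_threshold)
        mu = x_tr[:, sel].mean(axis=0)
        sd = x_tr[:, sel].std(axis=0)
        sd[sd == 0] = 1.0
        x_tr_s = (x_tr[:, sel] - mu) / sd
        x_te_s = (values[hold, sel] - mu) / sd
        clf = SVC(
            kernel=_SKLEARN_KERNEL[kernel],
            C=c,
            degree=3,
            gamma="auto",  # libsvm default 1/n_features
            coef0=0.0,
        )
        clf.fit(x_tr_s, y_tr)
        preds[hold] = int(clf.predict(x_te_s[None, :])[0])
        decisions[hold] = float(clf.decision_function(x_te_s[None, :])[0])
    return preds, decisions


def _confusion_rates(labels: np.ndarray, preds: np.ndarray) -> tuple[float, float, float]:
    tp = int(((labels == 1) & (preds == 1)).sum())
    tn = int(((labels == 0) & (preds == 0)).sum())
    fp = int(((labels == 0) & (preds == 1)).sum())
    fn = int(((labels == 1) & (preds == 0)).sum())
    acc = (tp + tn) / labels.size
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return acc, sens, spec


def loocv_svm(
    features: FeatureMatrix,
    kernels: tuple[str, ...] = DEFAULT_KERNELS,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    p_threshold: float = 0.05,
    seed: int = 0,
    leaky: bool = False,
) -> ClassificationResult:
    """Leave-one-subject-out SVM over the kernel/C grid.

    Feature selection and z-scoring are refit inside every fold (unless
    ``leaky=True``, which selects once on all subjects — provided only
    as the biased comparison).  The grid maximiser is reported with ties
    broken toward smaller C, then kernel order linear < polynomial <
    rbf.  AUC is computed from the pooled cross-validated decision
    values of the winning grid point.
    """
    values, labels = features.values, features.labels
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise InsufficientSubjectsError("need >= 2 subjects per class")
    leaky_sel = (
        _select_or_fallback(values, labels, p_threshold) if leaky else None
    )
    grid: dict[tuple[str, float], float] = {}
    best = None
    for kernel in sorted(kernels, key=_KERNEL_ORDER.__getitem__):
        for c in sorted(C_grid):
            preds, decisions = _loocv_single(
                values, labels, kernel, c, p_threshold, leaky_sel
            )
            acc, sens, spec = _confusion_rates(labels, preds)
            grid[(kernel, c)] = acc
            if best is None or acc > best[0]:
                best = (acc, sens, spec, kernel, c, preds, decisions)
    acc, sens, spec, kernel, c, preds, decisions = best
    if len(set(labels.tolist())) == 2 and len(set(decisions.tolist())) > 1:
        auc = float(roc_auc_score(labels, decisions))
    else:
        auc = 0.5
    return ClassificationResult(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        best_kernel=kernel,
        best_C=c,
        per_fold_predictions=preds,
        decision_values=decisions,
        grid=grid,
    )


def permutation_test_accuracy(
    features: FeatureMatrix,
    observed_accuracy: float,
    n_perm: int = 100,
    seed: int = 0,
    kernels: tuple[str, ...] = DEFAULT_KERNELS,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    p_threshold: float = 0.05,
) -> float:
    """Label-permutation p-value for an observed LOOCV accuracy.

    Each permutation shuffles the class labels and repeats the full
    grid LOOCV; p = (1 + #{permuted accuracy >= observed}) / (1 + n_perm).
    """
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_labels = rng.permutation(features.labels)
        perm_features = FeatureMatrix(
            features.values, perm_labels, features.feature_index
        )
        res = loocv_svm(
            perm_features, kernels=kernels, C_grid=C_grid, p_threshold=p_threshold
        )
        if res.accuracy >= observed_accuracy:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def metric_roc(values_class0: np.ndarray, values_class1: np.ndarray) -> ROCCurveResult:
    """ROC/AUC for a single scalar metric compared between two groups.

    The threshold sweep covers the pooled values; orientation is chosen
    so AUC >= 0.5, with the direction recorded.  AUC equals the
    Mann-Whitney probability that a random class-1 subject exceeds a
    random class-0 subject.
    """
    v0 = np.asarray(values_class0, dtype=float)
    v1 = np.asarray(values_class1, dtype=float)
    if v0.size == 0 or v1.size == 0:
        raise EmptyClassError("both classes need at least one value")
    y = np.concatenate([np.zeros(v0.size), np.ones(v1.size)])
    scores = np.concatenate([v0, v1])
    auc = float(roc_auc_score(y, scores))
    direction = "class1_higher"
    if auc < 0.5:
        scores = -scores
        auc = 1.0 - auc
        direction = "class0_higher"
    fpr, tpr, thresholds = roc_curve(y, scores)
    return ROCCurveResult(thresholds, tpr, fpr, auc, direction)


def lda_screen(features: FeatureMatrix, ridge: float = 1e-6) -> float:
    """Fisher-discriminant separation between the two classes.

    Returns the Mahalanobis distance between class means under the
    pooled within-class covariance (ridge-regularised relative to its
    mean diagonal, so the score is invariant to common rescaling of the
    features).  One feature with a 4-SD mean shift scores ~4.
    """
    x0 = features.values[features.labels == 0]
    x1 = features.values[features.labels == 1]
    if x0.shape[0] < 2 or x1.shape[0] < 2:
        raise InsufficientSubjectsError("need >= 2 subjects per class")
    n0, n1 = x0.shape[0], x1.shape[0]
    sw = ((n0 - 1) * np.cov(x0, rowvar=False) + (n1 - 1) * np.cov(x1, rowvar=False)) / (
        n0 + n1 - 2
    )
    sw = np.atleast_2d(sw)
    scale = np.trace(sw) / sw.shape[0]
    sw_reg = sw + ridge * max(scale, np.finfo(float).tiny) * np.eye(sw.shape[0])
    diff = x1.mean(axis=0) - x0.mean(axis=0)
    score2 = float(diff @ np.linalg.solve(sw_reg, diff))
    return float(np.sqrt(max(score2, 0.0)))
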