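"""Linear SVM classification, cross-validation folds, and baselines.

The classifier throughout is a soft-margin linear SVM (C = 1 by default)
with class labels -1/+1, so the decision threshold of h'x + b is 0.
Performance is summarized by accuracy at that threshold and the AUC of the
ROC curve of the continuous decision scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ClassifierModel",
    "FoldPlan",
    "EvalResult",
    "train_svm",
    "evaluate",
    "make_folds",
    "cross_validate_svm",
    "pca_svm_baseline",
]

DEFAULT_C = 1.0


@dataclass
class ClassifierModel:
    """A trained linear SVM: decision score h'x + b.

    ``alpha`` holds the dual coefficients per training subject (0 for
    non-support vectors); ``alpha_signed`` is alpha_i * y_i, so the primal
    normal is ``h = X_train.T @ alpha_signed``.
    """

    h: np.ndarray
    b: float
    C: float
    alpha: np.ndarray
    alpha_signed: np.ndarray
    support_index: np.ndarray

    @property
    def n_features(self) -> int:
        return self.h.size

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.h + self.b


@dataclass
class FoldPlan:
    """A k-fold partition of subjects (fold id per subject)."""

    k: int
    assignments: np.ndarray
    seed: int
    stratified: bool = True

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        sizes = np.bincount(self.assignments, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    def split(self):
        """Yield (train_idx, test_idx) per fold, in fold-id order."""
        for f in range(self.k):
            test = np.flatnonzero(self.assignments == f)
            train = np.flatnonzero(self.assignments != f)
            yield train, test


@dataclass
class EvalResult:
    """Accuracy at threshold 0, AUC of decision scores, and the scores."""

    accuracy: float
    auc: float
    scores: np.ndarray = field(repr=False, default=None)


def train_svm(X: np.ndarray, y: np.ndarray, C: float = DEFAULT_C) -> ClassifierModel:
    """Fit a soft-margin linear SVM on -1/+1 labels.

    Exposes the dual coefficients so the back-projection identity
    h = sum_i alpha_i y_i x_i can be checked and used for voxel weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    if C <= 0:
        raise ValueError("C must be > 0")
    svc = SVC(kernel="linear", C=C)
    svc.fit(X, y)
    n = X.shape[0]
    alpha_signed = np.zeros(n)
    alpha_signed[svc.support_] = svc.dual_coef_[0]
    # sklearn's dual_coef_ is alpha_i * y_i for the positive class ordering
    alpha = np.abs(alpha_signed)
    return ClassifierModel(
        h=svc.coef_[0].copy(),
        b=float(svc.intercept_[0]),
        C=C,
        alpha=alpha,
        alpha_signed=alpha_signed,
        support_index=svc.support_.copy(),
    )


def evaluate(model: ClassifierModel, X_test: np.ndarray, y_test: np.ndarray) -> EvalResult:
    """Accuracy (sign(0) counted as +1) and rank-statistic AUC on a test set."""
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise ValueError("empty test set")
    scores = model.decision(X_test)
    pred = np.where(scores >= 0, 1, -1)
    accuracy = float(np.mean(pred == y_test))
    auc = scores_auc(y_test, scores)
    return EvalResult(accuracy=accuracy, auc=auc, scores=scores)


def scores_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC of continuous scores; 0.5 when only one class is present."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        return 0.5
    return float(roc_auc_score(y, scores))


def make_folds(n: int, k: int, y: np.ndarray, seed: int, stratified: bool = True) -> FoldPlan:
    """Deterministic (optionally stratified) k-fold partition of n subjects.

    Falls back to unstratified folds with a warning when some class has
    fewer than k members.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need n >= k")
    y = np.asarray(y)
    if y.size != n:
        raise ValueError("labels length must be n")
    use_strat = stratified
    if stratified and np.bincount(np.unique(y, return_inverse=True)[1]).min() < k:
        warnings.warn("a class has fewer than k members; using unstratified folds")
        use_strat = False
    if use_strat:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(splitter.split(np.zeros((n, 1)), y)):
        assignments[test] = f
    return FoldPlan(k=k, assignments=assignments, seed=seed, stratified=use_strat)


def cross_validate_svm(
    X: np.ndarray, y: np.ndarray, folds: FoldPlan, C: float = DEFAULT_C
) -> tuple[list[EvalResult], EvalResult]:
    """Per-fold SVM train/test plus a pooled-score summary.

    The pooled summary concatenates every fold's test scores and computes
    one accuracy/AUC over all subjects (each subject is a test case exactly
    once).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    per_fold: list[EvalResult] = []
    pooled_scores = np.empty(y.size)
    for train, test in folds.split():
        model = train_svm(X[train], y[train], C=C)
        res = evaluate(model, X[test], y[test])
        per_fold.append(res)
        pooled_scores[test] = res.scores
    pooled_pred = np.where(pooled_scores >= 0, 1, -1)
    pooled = EvalResult(
        accuracy=float(np.mean(pooled_pred == y)),
        auc=scores_auc(y, pooled_scores),
        scores=pooled_scores,
    )
    return per_fold, pooled


def pca_svm_baseline(
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldPlan,
    n_components: int,
    C: float = DEFAULT_C,
) -> tuple[list[EvalResult], EvalResult]:
    """PCA (fit on training rows only) followed by linear SVM, per fold.

    Returns the per-fold results and their mean accuracy/AUC.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    per_fold: list[EvalResult] = []
    for train, test in folds.split():
        max_comp = min(train.size - 1, X.shape[1])
        if n_components > max_comp:
            raise ValueError(
                f"n_components={n_components} exceeds limit {max_comp} for this fold"
            )
        pca = PCA(n_components=n_components, svd_solver="full")
        Z_train = pca.fit_transform(X[train])
        Z_test = pca.transform(X[test])
        model = train_svm(Z_train, y[train], C=C)
        per_fold.append(evaluate(model, Z_test, y[test]))
    mean = EvalResult(
        accuracy=float(np.mean([r.accuracy for r in per_fold])),
        auc=float(np.mean([r.auc for r in per_fold])),
    )
    return per_fold, mean
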