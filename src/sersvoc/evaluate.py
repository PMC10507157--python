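"""Classification assessment and the PCA baseline.

Confusion matrix with row-normalized per-class accuracies (the
diagonal is per-class recall), one-vs-rest ROC curves with trapezoidal
AUC (equal to the Mann-Whitney pair statistic, ties credited 0.5),
macro-average AUC (unweighted mean over classes) and micro-average AUC
(pooled probability/indicator pairs), plus a from-scratch SVD-based
PCA over raw intensities as the linear baseline the network is
compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError("counts shape must be (k, k)")
        if np.any(self.counts < 0):
            raise ValueError("negative count")

    @property
    def normalized(self) -> np.ndarray:
        """Row-normalized matrix; all-zero rows stay all-zero."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else 0.0


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class EvalReport:
    accuracy: float
    confusion: ConfusionMatrix
    per_class_auc: dict[str, float]
    macro_auc: float
    micro_auc: float
    curves: dict[str, RocCurve] = field(default_factory=dict)


@dataclass
class PcaResult:
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray


def confusion_matrix(true_labels, predicted_labels, class_order) -> ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    k = len(class_order)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(class_order))


def roc_curve(scores, labels) -> RocCurve:
    """One-vs-rest ROC by threshold sweep over the unique scores.

    ``labels`` are binary indicators (1 = positive class).  Tied
    scores collapse onto one threshold, which is what gives the
    trapezoidal AUC its Mann-Whitney half-credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep the last index of each tied-score run
    last = np.r_[np.flatnonzero(np.diff(s) != 0), s.size - 1]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    thresholds = np.r_[np.inf, s[last]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def evaluate_model(model, X, true_labels, class_order=None) -> EvalReport:
    """Full assessment of a fitted probabilistic classifier.

    ``model`` needs ``predict_proba`` and ``classes_``; probabilities
    are used both for predictions (argmax) and the ROC family.
    """
    true_labels = np.asarray(list(true_labels))
    if true_labels.size == 0:
        raise ValueError("empty test set")
    classes = tuple(class_order) if class_order is not None else tuple(model.classes_)
    if len(set(true_labels)) < 2:
        raise ValueError("test set needs at least 2 classes")
    proba = np.asarray(model.predict_proba(X))
    model_classes = list(model.classes_)
    col = {c: model_classes.index(c) for c in classes}
    predicted = np.asarray(model_classes)[np.argmax(proba, axis=1)]
    cm = confusion_matrix(true_labels, predicted, classes)

    per_class: dict[str, float] = {}
    curves: dict[str, RocCurve] = {}
    pooled_scores, pooled_labels = [], []
    for c in classes:
        indicator = (true_labels == c).astype(int)
        scores = proba[:, col[c]]
        pooled_scores.append(scores)
        pooled_labels.append(indicator)
        if indicator.sum() in (0, indicator.size):
            continue  # class absent from this test set: no curve
        curve = roc_curve(scores, indicator)
        curves[c] = curve
        per_class[c] = curve.auc
    macro = float(np.mean(list(per_class.values())))
    micro_curve = roc_curve(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return EvalReport(
        accuracy=cm.accuracy,
        confusion=cm,
        per_class_auc=per_class,
        macro_auc=macro,
        micro_auc=micro_curve.auc,
        curves=curves,
    )


def pca_scores(X, n_components: int = 3) -> PcaResult:
    """PCA of raw intensities by SVD of the column-centered matrix.

    Each component is oriented so its largest-magnitude loading is
    positive, making score signs reproducible across SVD backends.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} samples")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    comps = Vt[:n_components]
    scores = U[:, :n_components] * s[:n_components]
    signs = np.sign(comps[np.arange(n_components), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    comps = comps * signs[:, None]
    scores = scores * signs[None, :]
    ratio = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return PcaResult(scores=scores, explained_variance_ratio=ratio, loadings=comps)
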