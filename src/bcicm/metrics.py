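"""Binary classification metrics, ROC/AUC, and cluster-to-class alignment.

The convention throughout: a malignant sample is a positive (P) outcome and
a benign sample a negative (N) one.  Metrics are reported as percentages:

    ACC = (TP + TN) / (P + N) * 100
    SEN = TP / (TP + FN) * 100
    PRE = TP / (TP + FP) * 100
    SPE = TN / (TN + FP) * 100
    F1  = 2 * PRE * SEN / (PRE + SEN)

Note on SEN: a published variant of the sensitivity formula with TP + TN in
the denominator is internally inconsistent with any confusion matrix whose
SEN and SPE differ; the standard TP/(TP+FN) is used here (it reproduces all
consistency identities such as balanced-class ACC = (SEN+SPE)/2).

For a hard (single-threshold) classifier the ROC curve has one interior
vertex and its trapezoidal AUC equals (SEN + SPE)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import InvalidInputError, UndefinedMetricError

BENIGN, MALIGNANT = "benign", "malignant"
_VALID_LABELS = {BENIGN, MALIGNANT}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.positives + self.negatives


@dataclass(frozen=True)
class MetricsReport:
    """The six headline metrics, each a percentage in [0, 100]."""

    acc: float
    sen: float
    pre: float
    spe: float
    f1: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def plot(self, ax=None, label: str | None = None):
        """Plot the curve on a matplotlib axis (created if absent)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, label=label)
        ax.plot([0, 1], [0, 1], linestyle=":", color="gray")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        if label:
            ax.legend()
        return ax


def _check_labels(labels) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    unknown = set(arr.tolist()) - _VALID_LABELS
    if unknown:
        raise InvalidInputError(f"unknown class labels: {sorted(map(str, unknown))}")
    return arr


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Tally a confusion matrix with malignant as the positive class."""
    yt, yp = _check_labels(y_true), _check_labels(y_pred)
    if yt.shape != yp.shape or yt.size == 0:
        raise InvalidInputError("y_true and y_pred must be equal-length and non-empty")
    t_pos, p_pos = yt == MALIGNANT, yp == MALIGNANT
    return ConfusionMatrix(
        tp=int(np.sum(t_pos & p_pos)),
        fn=int(np.sum(t_pos & ~p_pos)),
        tn=int(np.sum(~t_pos & ~p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
    )


def _ratio(num: int, den: int, metric: str) -> float:
    if den == 0:
        raise UndefinedMetricError(metric)
    return 100.0 * num / den


def acc(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp + cm.tn, cm.total, "acc")


def sen(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fn, "sen")


def pre(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fp, "pre")


def spe(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tn, cm.tn + cm.fp, "spe")


def f1(cm: ConfusionMatrix) -> float:
    p, s = pre(cm), sen(cm)
    if p + s == 0:
        raise UndefinedMetricError("f1")
    return 2.0 * p * s / (p + s)


def hard_classifier_auc(cm: ConfusionMatrix) -> float:
    """Trapezoidal AUC of the two-segment ROC through one operating point:
    (SEN + SPE) / 2, as a percentage."""
    return (sen(cm) + spe(cm)) / 2.0


def report(cm: ConfusionMatrix, auc: float | None = None) -> MetricsReport:
    """All six metrics from a confusion matrix; AUC defaults to the
    hard-classifier trapezoid identity when no continuous score is given."""
    return MetricsReport(
        acc=acc(cm),
        sen=sen(cm),
        pre=pre(cm),
        spe=spe(cm),
        f1=f1(cm),
        auc=auc if auc is not None else hard_classifier_auc(cm),
    )


def margin_score(
    points: np.ndarray, benign_center: np.ndarray, malignant_center: np.ndarray
) -> np.ndarray:
    """Continuous malignancy score per point:
    dist(point, benign center) - dist(point, malignant center).

    Positive leans malignant; thresholding at 0 reproduces the
    nearest-center hard assignment (after cluster-to-class alignment).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    b = np.asarray(benign_center, dtype=float)
    m = np.asarray(malignant_center, dtype=float)
    if b.shape != (pts.shape[1],) or m.shape != (pts.shape[1],):
        raise InvalidInputError("center dimensions must match the points")
    return np.linalg.norm(pts - b, axis=1) - np.linalg.norm(pts - m, axis=1)


def roc_auc(scores, y_true) -> tuple[RocCurve, float]:
    """Threshold-sweep ROC with trapezoidal AUC (as a percentage)."""
    from sklearn.metrics import roc_curve

    yt = _check_labels(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != yt.shape:
        raise InvalidInputError("scores and labels must be equal-length")
    y_bin = (yt == MALIGNANT).astype(int)
    if y_bin.min() == y_bin.max():
        raise UndefinedMetricError("auc", "ROC requires both classes present")
    fpr, tpr, thr = roc_curve(y_bin, scores)
    auc = float(np.trapezoid(tpr, fpr)) * 100.0
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr), auc


def align_clusters(clusters, y_true) -> dict[int, str]:
    """Map cluster indices {0, 1} to class labels, maximizing accuracy.

    Of the two possible mappings the more accurate one is returned; an exact
    tie yields the identity mapping (0 -> benign, 1 -> malignant).
    """
    cl = np.asarray(clusters, dtype=int)
    yt = _check_labels(y_true)
    if cl.shape != yt.shape or cl.size == 0:
        raise InvalidInputError("clusters and labels must be equal-length and non-empty")
    identity = {0: BENIGN, 1: MALIGNANT}
    swapped = {0: MALIGNANT, 1: BENIGN}
    hits_id = int(np.sum(np.array([identity[c] for c in cl], dtype=object) == yt))
    hits_sw = int(np.sum(np.array([swapped[c] for c in cl], dtype=object) == yt))
    return identity if hits_id >= hits_sw else swapped
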