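"""Segmentation/classification metrics, ROC thresholding, Bland-Altman.

Segmentation overlap is summarized from per-pixel confusion counts
(Dice, Jaccard, accuracy); classifier performance by AUROC,
sensitivity, specificity and predictive values at a threshold chosen as
the ROC point closest to the top-left corner; and agreement between two
measurements of the same quantity by Bland-Altman bias and limits of
agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class DiagnosticSummary:
    auroc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float


@dataclass
class AgreementReport:
    bias: float
    loa_low: float
    loa_high: float


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------

def dice(c: ConfusionCounts) -> float:
    """Dice coefficient 2*TP / (2*TP + FP + FN)."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise UndefinedMetricError("Dice undefined: 2*TP + FP + FN = 0")
    return 2 * c.tp / denom


def jaccard(c: ConfusionCounts) -> float:
    """Jaccard index TP / (TP + FP + FN)."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        raise UndefinedMetricError("Jaccard undefined: TP + FP + FN = 0")
    return c.tp / denom


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: no counts")
    return (c.tp + c.tn) / c.total


def confusion_from_masks(pred: np.ndarray, truth: np.ndarray, positive_label: int,
                         ) -> ConfusionCounts:
    """Pixel-pooled confusion counts for one class of two label images."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    p = pred == positive_label
    t = truth == positive_label
    return ConfusionCounts(tp=int((p & t).sum()), tn=int((~p & ~t).sum()),
                           fp=int((p & ~t).sum()), fn=int((~p & t).sum()))


def segmentation_summary(pred: np.ndarray, truth: np.ndarray,
                         labels=(1, 2)) -> dict[int, dict[str, float]]:
    """Dice/Jaccard/accuracy per class, pooled over all pixels.

    For label 1 the "class" is the full disc region (labels >= 1, cup
    included); for label 2 it is the cup.
    """
    out = {}
    for lab in labels:
        if lab == 1:
            c = confusion_from_masks(np.asarray(pred) >= 1, np.asarray(truth) >= 1, True)
        else:
            c = confusion_from_masks(pred, truth, lab)
        out[lab] = {"dice": dice(c), "jaccard": jaccard(c), "accuracy": accuracy(c)}
    return out


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return labels


def roc_auroc(scores, labels) -> float:
    """AUROC by the rank (Mann-Whitney) formulation with midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # midranks
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted scores, plus +/-inf."""
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _sens_spec(scores, labels, thr):
    pred = scores >= thr
    pos, neg = labels, ~labels
    sens = (pred & pos).sum() / pos.sum()
    spec = (~pred & neg).sum() / neg.sum()
    return float(sens), float(spec)


def optimal_threshold(scores, labels) -> float:
    """Cut-point closest (Euclidean) to the ROC's top-left corner.

    Ties are resolved in favour of higher sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    best_thr, best_d, best_sens = None, np.inf, -1.0
    for thr in _candidate_thresholds(scores):
        sens, spec = _sens_spec(scores, labels, thr)
        d = math.hypot(1.0 - sens, 1.0 - spec)
        if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and sens > best_sens):
            best_thr, best_d, best_sens = thr, d, sens
    return float(best_thr)


def diagnostic_summary(scores, labels, threshold: float | None = None,
                       ) -> DiagnosticSummary:
    """Sens/spec/PPV/NPV at a (>=) threshold, plus AUROC.

    With ``threshold=None`` the ROC-optimal threshold is used.  An empty
    predicted class makes the corresponding predictive value NaN
    (undefined), not zero.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    if threshold is None:
        threshold = optimal_threshold(scores, labels)
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    return DiagnosticSummary(
        auroc=roc_auroc(scores, labels),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if tp + fp > 0 else float("nan"),
        npv=tn / (tn + fn) if tn + fn > 0 else float("nan"),
        threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

def bland_altman(values_a, values_b) -> AgreementReport:
    """Bland-Altman agreement: bias and 1.96-SD limits of differences a - b."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D paired samples")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementReport(bias=bias, loa_low=bias - 1.96 * sd,
                           loa_high=bias + 1.96 * sd)


# ---------------------------------------------------------------------------
# optional plots
# ---------------------------------------------------------------------------

def save_roc_plot(scores, labels, path) -> None:
    """Write an empirical ROC curve plot with its AUROC in the title."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    pts = sorted(_sens_spec(scores, labels, t) for t in _candidate_thresholds(scores))
    fpr = [1 - spec for _, spec in pts]
    tpr = [sens for sens, _ in pts]
    order = np.argsort(fpr)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(np.asarray(fpr)[order], np.asarray(tpr)[order], marker=".")
    ax.plot([0, 1], [0, 1], ls="--", c="gray")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUROC = {roc_auroc(scores, labels):.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_bland_altman_plot(values_a, values_b, path) -> None:
    """Write a Bland-Altman scatter with bias and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    rep = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, a - b, s=10, alpha=0.6)
    for y, ls in ((rep.bias, "-"), (rep.loa_low, "--"), (rep.loa_high, "--")):
        ax.axhline(y, ls=ls, c="crimson")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (a - b)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
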