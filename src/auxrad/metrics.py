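"""Confusion matrices, printed-formula metrics, hierarchical collapsing,
and one-vs-rest ROC AUC.

The class order everywhere is (normal, A1, A2, A3, B1, B2, B3); rows of a
confusion matrix are actual classes, columns are predicted classes.  The
AO/OTA hierarchy collapses the seven fine labels to three groups
(normal / A trochanteric / B neck) and to two (normal / fracture).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import CLASS_NAMES

FINE_TO_MID = {0: 0, 1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2}   # normal, A, B
MID_TO_COARSE = {0: 0, 1: 1, 2: 1}                          # normal, fracture
LEVEL_NAMES = {
    7: CLASS_NAMES,
    3: ("normal", "A", "B"),
    2: ("normal", "fracture"),
}


def confusion_matrix(y_true, y_pred, k: int) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty label sequences")
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    if (y_true < 0).any() or (y_true >= k).any() or \
       (y_pred < 0).any() or (y_pred >= k).any():
        raise ValueError(f"labels out of range [0, {k})")
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def per_class_counts(cm: np.ndarray, c: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, FN, TN) for class ``c``."""
    cm = np.asarray(cm)
    if not 0 <= c < cm.shape[0]:
        raise ValueError(f"class {c} out of range")
    tp = int(cm[c, c])
    fp = int(cm[:, c].sum() - tp)
    fn = int(cm[c, :].sum() - tp)
    tn = int(cm.sum() - tp - fp - fn)
    return tp, fp, fn, tn


@dataclass
class MetricsReport:
    level: int
    accuracy: float
    precision: list
    recall: list
    f1: list
    avg_f1: float
    counts: list                      # per-class (TP, FP, FN, TN)
    undefined: list = field(default_factory=list)  # (class, metric) flags
    class_names: tuple = ()


def _safe_div(num, den, flags, c, name):
    if den == 0:
        flags.append((c, name))
        return 0.0
    return num / den


def metrics(cm: np.ndarray) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1 (one-vs-rest), macro F1.

    Zero-denominator ratios are reported as 0 and flagged in
    ``undefined`` -- necessary for extremely rare classes that a model
    may never predict.
    """
    cm = np.asarray(cm)
    k = cm.shape[0]
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    flags: list = []
    precision, recall, f1, counts = [], [], [], []
    for c in range(k):
        tp, fp, fn, tn = per_class_counts(cm, c)
        p = _safe_div(tp, tp + fp, flags, c, "precision")
        r = _safe_div(tp, tp + fn, flags, c, "recall")
        f = _safe_div(2 * p * r, p + r, flags, c, "f1")
        precision.append(p); recall.append(r); f1.append(f)
        counts.append((tp, fp, fn, tn))
    return MetricsReport(
        level=k,
        accuracy=float(np.trace(cm) / total),
        precision=precision, recall=recall, f1=f1,
        avg_f1=float(np.mean(f1)),
        counts=counts, undefined=flags,
        class_names=LEVEL_NAMES.get(k, tuple(str(i) for i in range(k))))


def collapse(cm_fine: np.ndarray, mapping: dict[int, int], k_out: int
             ) -> np.ndarray:
    """Collapse a confusion matrix along a label hierarchy; totals conserved."""
    cm_fine = np.asarray(cm_fine)
    k_in = cm_fine.shape[0]
    if set(mapping) != set(range(k_in)):
        raise ValueError("mapping must cover every fine label")
    out = np.zeros((k_out, k_out), dtype=cm_fine.dtype)
    for i in range(k_in):
        for j in range(k_in):
            out[mapping[i], mapping[j]] += cm_fine[i, j]
    return out


def collapse_labels(labels: np.ndarray, level: int) -> np.ndarray:
    """Map 7-class labels to the 3- or 2-class level."""
    labels = np.asarray(labels, dtype=int)
    if level == 7:
        return labels
    mid = np.array([FINE_TO_MID[i] for i in range(7)])[labels]
    if level == 3:
        return mid
    if level == 2:
        return np.array([MID_TO_COARSE[i] for i in range(3)])[mid]
    raise ValueError("level must be 2, 3, or 7")


def collapse_cm(cm7: np.ndarray, level: int) -> np.ndarray:
    if level == 7:
        return np.asarray(cm7)
    if level == 3:
        return collapse(cm7, FINE_TO_MID, 3)
    if level == 2:
        mid = collapse(cm7, FINE_TO_MID, 3)
        return collapse(mid, MID_TO_COARSE, 2)
    raise ValueError("level must be 2, 3, or 7")


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """One-vs-rest AUC via the rank (Mann-Whitney) formula.

    Equals the probability that a random positive outscores a random
    negative, counting ties as 1/2.  Raises on single-class input.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty_like(s)
    ranks[order] = np.arange(1, len(s) + 1)
    # average ranks over ties
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        if j > i:
            ranks[order[i:j + 1]] = (i + 1 + j + 1) / 2.0
        i = j + 1
    rank_sum = ranks[y == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def one_vs_rest_auc(y_true: np.ndarray, proba: np.ndarray) -> dict[int, float | None]:
    """Per-class AUC on softmax scores; ``None`` where a class is absent."""
    y = np.asarray(y_true, dtype=int)
    out: dict[int, float | None] = {}
    for c in range(proba.shape[1]):
        binary = (y == c).astype(int)
        try:
            out[c] = roc_auc(binary, proba[:, c])
        except ValueError:
            out[c] = None
    return out


def format_cm(cm: np.ndarray, names) -> str:
    """Plain-text confusion-matrix table (rows actual, columns predicted)."""
    w = max(6, max(len(n) for n in names) + 1)
    lines = [" " * w + "".join(f"{n:>{w}}" for n in names)]
    for i, n in enumerate(names):
        lines.append(f"{n:>{w}}" + "".join(f"{cm[i, j]:>{w}}" for j in range(len(names))))
    return "\n".join(lines)
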