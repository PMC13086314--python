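"""Imbalance-aware evaluation: confusion matrices, macro metrics, PR curves.

Overall accuracy hides failure on rare classes, so the macro family
(macro precision MP, macro recall MR, macro F1 MF) averages the
per-class rates with equal class weight.  MF is the mean of per-class
F1 values, not the harmonic mean of MP and MR.  A class with an empty
denominator (never predicted, or with no true samples) contributes 0 to
the macro mean — a deliberate penalty for degenerate predictors on
imbalanced data rather than silently dropping the class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ZERO_DENOM_CONVENTION = ("classes with an empty precision/recall denominator "
                         "contribute 0 to the macro mean")
SD_CONVENTION = "sample standard deviation (n-1 denominator; 0 for n=1)"


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be nonnegative")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.n - self.tp - self.fn - self.fp

    def normalized(self) -> np.ndarray:
        """Row-normalized matrix (each true class sums to 1; empty rows 0)."""
        row = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(row > 0, self.counts / row, 0.0)
        return out


def confusion(y_true, y_pred, k: int) -> ConfusionMatrix:
    """Count matrix[i][j] = number of samples with true class i predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        bad = np.nonzero((arr < 0) | (arr >= k))[0]
        if bad.size:
            raise ValueError(f"{name}[{bad[0]}] = {arr[bad[0]]} outside [0, {k})")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def _check_nonempty(cm: ConfusionMatrix) -> None:
    if cm.n == 0:
        raise ValueError("confusion matrix is empty (n = 0)")


def accuracy(cm: ConfusionMatrix) -> float:
    _check_nonempty(cm)
    return float(cm.tp.sum() / cm.n)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros(len(num), dtype=float)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def per_class_precision(cm: ConfusionMatrix) -> np.ndarray:
    return _safe_ratio(cm.tp, cm.tp + cm.fp)


def per_class_recall(cm: ConfusionMatrix) -> np.ndarray:
    return _safe_ratio(cm.tp, cm.tp + cm.fn)


def per_class_f1(cm: ConfusionMatrix) -> np.ndarray:
    return _safe_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn)


def macro_precision(cm: ConfusionMatrix) -> float:
    _check_nonempty(cm)
    return float(per_class_precision(cm).mean())


def macro_recall(cm: ConfusionMatrix) -> float:
    _check_nonempty(cm)
    return float(per_class_recall(cm).mean())


def macro_f1(cm: ConfusionMatrix) -> float:
    _check_nonempty(cm)
    return float(per_class_f1(cm).mean())


# ---------------------------------------------------------------------------
# precision-recall curves (one-vs-rest)
# ---------------------------------------------------------------------------

def pr_curve(scores: np.ndarray, y_true, class_index: int):
    """One-vs-rest PR points swept over the distinct scores of one class.

    ``scores`` is (n_samples, k) of raw per-class scores.  Returns a list
    of (recall, precision) points ordered by descending threshold, so
    recall is nondecreasing along the list.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=np.int64)
    s = scores[:, class_index]
    pos = y_true == class_index
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError(f"class {class_index} has no positive samples; "
                         "PR curve undefined")
    points = []
    for thr in np.unique(s)[::-1]:
        pred = s >= thr
        tp = int((pred & pos).sum())
        fp = int((pred & ~pos).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / n_pos
        points.append((recall, precision))
    return points


def pr_auc(points) -> float:
    """Area under a PR point list by the rectangle rule (AP-style)."""
    area, prev_r = 0.0, 0.0
    for r, p in points:
        area += (r - prev_r) * p
        prev_r = r
    return area


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Acc/MP/MR/MF plus per-class rates for one evaluation run."""

    acc: float
    mp: float
    mr: float
    mf: float
    per_class: list[dict] = field(default_factory=list)
    class_names: list[str] | None = None
    confusion_matrix: ConfusionMatrix | None = None
    conventions: dict = field(default_factory=lambda: {
        "zero_denominator": ZERO_DENOM_CONVENTION, "sd": SD_CONVENTION})

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix,
                       class_names: list[str] | None = None) -> "MetricsReport":
        prec, rec, f1 = per_class_precision(cm), per_class_recall(cm), per_class_f1(cm)
        per_class = [
            {"class": class_names[i] if class_names else i,
             "precision": float(prec[i]), "recall": float(rec[i]),
             "f1": float(f1[i]), "support": int(cm.tp[i] + cm.fn[i])}
            for i in range(cm.k)]
        return cls(acc=accuracy(cm), mp=macro_precision(cm), mr=macro_recall(cm),
                   mf=macro_f1(cm), per_class=per_class, class_names=class_names,
                   confusion_matrix=cm)

    def to_dict(self) -> dict:
        out = {"acc": self.acc, "mp": self.mp, "mr": self.mr, "mf": self.mf,
               "per_class": self.per_class, "conventions": self.conventions}
        if self.confusion_matrix is not None:
            out["confusion_matrix"] = self.confusion_matrix.counts.tolist()
        return out

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def aggregate_reports(reports: list[MetricsReport]) -> dict:
    """mean +/- sample SD of Acc/MP/MR/MF across replicate runs."""
    if not reports:
        raise ValueError("no reports to aggregate")
    out = {"n_replicates": len(reports), "sd_convention": SD_CONVENTION}
    for key in ("acc", "mp", "mr", "mf"):
        vals = [getattr(r, key) for r in reports]
        mean = sum(vals) / len(vals)
        if len(vals) > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        else:
            sd = 0.0
        out[key] = {"mean": mean, "sd": sd}
    return out


# ---------------------------------------------------------------------------
# artefacts (CSV / plots)
# ---------------------------------------------------------------------------

def confusion_to_csv(cm: ConfusionMatrix, path, class_names=None) -> None:
    names = class_names or [str(i) for i in range(cm.k)]
    lines = ["true\\pred," + ",".join(names)]
    for i, row in enumerate(cm.counts):
        lines.append(names[i] + "," + ",".join(str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def pr_points_to_csv(scores: np.ndarray, y_true, path, class_names=None) -> None:
    """One-vs-rest PR sweep points for every class with positives."""
    scores = np.asarray(scores)
    names = class_names or [str(i) for i in range(scores.shape[1])]
    lines = ["class,recall,precision"]
    for c in range(scores.shape[1]):
        try:
            pts = pr_curve(scores, y_true, c)
        except ValueError:
            continue
        lines.extend(f"{names[c]},{r},{p}" for r, p in pts)
    Path(path).write_text("\n".join(lines) + "\n")


def plot_confusion(cm: ConfusionMatrix, path, class_names=None) -> None:
    """Row-normalized confusion-matrix heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = class_names or [str(i) for i in range(cm.k)]
    norm = cm.normalized()
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(norm, cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(cm.k), names, rotation=45, ha="right")
    ax.set_yticks(range(cm.k), names)
    ax.set_xlabel("predicted"), ax.set_ylabel("true")
    for i in range(cm.k):
        for j in range(cm.k):
            ax.text(j, i, f"{norm[i, j]:.2f}", ha="center", va="center",
                    fontsize=7, color="black" if norm[i, j] < 0.6 else "white")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pr_curves(scores: np.ndarray, y_true, path, class_names=None) -> None:
    """One-vs-rest PR curves for every class with at least one positive."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.asarray(scores)
    k = scores.shape[1]
    names = class_names or [str(i) for i in range(k)]
    fig, ax = plt.subplots(figsize=(6, 5))
    for c in range(k):
        try:
            pts = pr_curve(scores, y_true, c)
        except ValueError:
            continue
        r = [0.0] + [p[0] for p in pts]
        p = [pts[0][1]] + [p[1] for p in pts]
        ax.plot(r, p, label=f"{names[c]} (AP={pr_auc(pts):.3f})")
    ax.set_xlabel("recall"), ax.set_ylabel("precision")
    ax.set_xlim(0, 1.02), ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
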