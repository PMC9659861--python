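"""Evaluation statistics for both classification stages.

Conventions (documented because the field uses several):

* ``Rec``/``Pre``/``F1`` are macro averages over classes; a class that is
  never predicted contributes precision 0.
* ``Top-1 Acc`` is trace / total on the confusion matrix.
* ``MAcc`` is the mean of per-class one-vs-rest accuracies
  ((TP + TN) / total averaged over classes).
* ROC/AUC is one-vs-rest per class with midrank tie handling (equivalent to
  the Mann-Whitney U statistic normalised by n_pos * n_neg).
* Binomial confidence intervals use the Wilson score method.
* McNemar's test uses the continuity-corrected chi-square statistic
  ``max(|b - c| - 1, 0)^2 / (b + c)`` (clamped so b = c gives statistic 0 and
  p = 1) with the asymptotic one-degree-of-freedom upper tail, two-sided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint


@dataclass
class ConfusionMatrix:
    """Integer K x K counts; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_names: list | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix entries must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int,
                         class_names=None) -> "ConfusionMatrix":
        counts = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
        return cls(counts=counts, class_names=class_names)


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Macro recall/precision/F1, Top-1 accuracy and mean per-class accuracy."""
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    tp = np.diag(counts)
    row = counts.sum(axis=1)   # true counts
    col = counts.sum(axis=0)   # predicted counts
    with np.errstate(divide="ignore", invalid="ignore"):
        rec_c = np.where(row > 0, tp / row, 0.0)
        pre_c = np.where(col > 0, tp / col, 0.0)
        f1_c = np.where(rec_c + pre_c > 0, 2 * rec_c * pre_c / (rec_c + pre_c), 0.0)
    tn = total - row - col + tp
    macc_c = (tp + tn) / total
    return {
        "Rec": float(rec_c.mean()),
        "Top1Acc": float(np.trace(cm.counts) / cm.total),
        "MAcc": float(macc_c.mean()),
        "Pre": float(pre_c.mean()),
        "F1": float(f1_c.mean()),
    }


def roc_auc(scores, truths) -> dict:
    """Per-class one-vs-rest AUC plus the macro average over defined classes.

    ``scores`` is (n, K) with rows summing to 1; a class absent from (or
    filling all of) ``truths`` has no defined AUC and is reported as None.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truths = np.asarray(truths)
    if np.any(np.abs(scores.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("score rows must sum to 1")
    k = scores.shape[1]
    per_class: dict[int, float | None] = {}
    for c in range(k):
        pos = truths == c
        if pos.all() or not pos.any():
            per_class[c] = None
            continue
        per_class[c] = float(roc_auc_score(pos.astype(int), scores[:, c]))
    defined = [v for v in per_class.values() if v is not None]
    macro = float(np.mean(defined)) if defined else None
    return {"per_class": per_class, "macro": macro}


def roc_points(scores_c, truths_binary):
    """(fpr, tpr, thresholds) for one class's score column, for plotting/CSV."""
    from sklearn.metrics import roc_curve

    return roc_curve(np.asarray(truths_binary).astype(int),
                     np.asarray(scores_c, dtype=np.float64))


def binom_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in [0, {n}], got {successes}")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    # Wilson endpoints are exactly 0 / 1 at the boundary proportions
    if successes == 0:
        lo = 0.0
    if successes == n:
        hi = 1.0
    return float(lo), float(hi)


@dataclass
class McNemarResult:
    b: int
    c: int
    statistic: float
    p: float
    defined: bool = True


def mcnemar(b: int, c: int) -> McNemarResult:
    """Two-sided McNemar test on discordant counts.

    ``b`` = first method correct / second wrong, ``c`` = the reverse. Uses the
    continuity-corrected statistic clamped at zero, so b = c gives statistic 0
    and p = 1. ``b + c = 0`` has no defined test (the methods never disagree)
    and is flagged via ``defined=False``.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    if b + c == 0:
        return McNemarResult(b=b, c=c, statistic=float("nan"), p=float("nan"),
                             defined=False)
    stat = max(abs(b - c) - 1.0, 0.0) ** 2 / (b + c)
    return McNemarResult(b=int(b), c=int(c), statistic=float(stat),
                         p=chisq1_pvalue(stat))


def chisq1_pvalue(stat: float) -> float:
    """Upper tail of chi-square with one degree of freedom: 2(1 - Phi(sqrt(x)))."""
    if stat < 0:
        raise ValueError("statistic must be >= 0")
    return float(2.0 * stats.norm.sf(np.sqrt(stat)))


@dataclass
class EvalReport:
    """Everything computed for one evaluated split."""

    confusion: ConfusionMatrix
    metrics: dict
    auc: dict
    per_class_stats: list = field(default_factory=list)
    mcnemar_vs_reference: dict | None = None

    @classmethod
    def from_predictions(cls, y_true, y_pred, scores=None, n_classes=None,
                         class_names=None, reference_pred=None) -> "EvalReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if n_classes is None:
            n_classes = int(max(y_true.max(), y_pred.max())) + 1
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, n_classes, class_names)
        metrics = classification_metrics(cm)
        auc = roc_auc(scores, y_true) if scores is not None else {
            "per_class": {}, "macro": None}
        per_class = []
        n = len(y_true)
        for c in range(n_classes):
            pos = y_true == c
            n_pos, n_neg = int(pos.sum()), int((~pos).sum())
            tp = int(((y_pred == c) & pos).sum())
            tn = int(((y_pred != c) & ~pos).sum())
            entry = {"class": c if class_names is None else class_names[c]}
            if n_pos:
                entry["sensitivity"] = tp / n_pos
                entry["sensitivity_ci"] = binom_ci(tp, n_pos)
            if n_neg:
                entry["specificity"] = tn / n_neg
                entry["specificity_ci"] = binom_ci(tn, n_neg)
            per_class.append(entry)
        mc = None
        if reference_pred is not None:
            ref = np.asarray(reference_pred)
            b = int(((y_pred == y_true) & (ref != y_true)).sum())
            c_ = int(((y_pred != y_true) & (ref == y_true)).sum())
            r = mcnemar(b, c_)
            mc = {"b": r.b, "c": r.c, "statistic": r.statistic, "p": r.p,
                  "defined": r.defined}
        return cls(confusion=cm, metrics=metrics, auc=auc,
                   per_class_stats=per_class, mcnemar_vs_reference=mc)

    def to_json(self) -> str:
        return json.dumps({
            "confusion": self.confusion.counts.tolist(),
            "class_names": self.confusion.class_names,
            "metrics": self.metrics,
            "auc": {"per_class": {str(k): v for k, v in self.auc["per_class"].items()},
                    "macro": self.auc["macro"]},
            "per_class_stats": self.per_class_stats,
            "mcnemar_vs_reference": self.mcnemar_vs_reference,
        }, indent=2)
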