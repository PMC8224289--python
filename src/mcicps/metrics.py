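"""Classification metrics: rank-formulation AUC, confusion metrics, ROC.

AUC uses the Mann-Whitney rank statistic with midrank tie correction,
which equals trapezoidal integration of the ROC curve.  Sensitivity is
computed on the positive (P-MCI, converter) class: Sn = TP / (TP + FN);
specificity on the stable class: Sp = TN / (TN + FP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve


@dataclass
class EvaluationReport:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fn: int
    tn: int
    fp: int
    n: int
    threshold: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    per_subtype: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "n": self.n, "threshold": self.threshold,
        }


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie correction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Accuracy / sensitivity / specificity from confusion counts."""
    n = tp + fn + tn + fp
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def evaluate(scores: np.ndarray, labels: np.ndarray, tau: float = 0.5,
             subtypes: np.ndarray | None = None) -> EvaluationReport:
    """Full evaluation of P-MCI probabilities against binary labels.

    Calls are P-MCI iff score >= tau.  When ``subtypes`` is given, the same
    metrics are reported per subtype (AUC only where both classes occur).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    auc = rank_auc(scores, labels)
    calls = (scores >= tau).astype(int)
    tp = int(((calls == 1) & (labels == 1)).sum())
    fn = int(((calls == 0) & (labels == 1)).sum())
    tn = int(((calls == 0) & (labels == 0)).sum())
    fp = int(((calls == 1) & (labels == 0)).sum())
    cm = confusion_metrics(tp, fn, tn, fp)
    fpr, tpr, _ = roc_curve(labels, scores)
    per_subtype: dict = {}
    if subtypes is not None:
        subtypes = np.asarray(subtypes)
        for s in np.unique(subtypes):
            m = subtypes == s
            entry = {"n": int(m.sum())}
            if len(np.unique(labels[m])) == 2:
                entry["auc"] = rank_auc(scores[m], labels[m])
            per_subtype[int(s)] = entry
    return EvaluationReport(auc, cm["accuracy"], cm["sensitivity"],
                            cm["specificity"], tp, fn, tn, fp,
                            int(labels.size), tau, fpr, tpr, per_subtype)
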