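"""Binary-classification metrics: AUC, accuracy, MCC, sensitivity, specificity."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class MetricsReport:
    auc: float
    acc: float
    mcc: float
    se: float        # sensitivity = TP / (TP + FN)
    sp: float        # specificity = TN / (TN + FP)
    tp: int
    tn: int
    fp: int
    fn: int
    n: int
    threshold: float = 0.5

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def compute_metrics(y_true, prob, threshold: float = 0.5) -> MetricsReport:
    """Metrics from true labels and predicted positive-class probabilities.

    AUC is the rank statistic over probabilities (undefined for single-class
    truth, reported as NaN); MCC is 0 whenever a denominator factor is 0.
    """
    y = np.asarray(y_true).astype(int)
    p = np.asarray(prob, dtype=float)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = y.shape[0]
    acc = (tp + tn) / n if n else float("nan")
    se = tp / (tp + fn) if (tp + fn) else float("nan")
    sp = tn / (tn + fp) if (tn + fp) else float("nan")
    denom = math.sqrt(max((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn), 0))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    auc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else float("nan")
    return MetricsReport(auc=auc, acc=acc, mcc=mcc, se=se, sp=sp,
                         tp=tp, tn=tn, fp=fp, fn=fn, n=n, threshold=threshold)
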