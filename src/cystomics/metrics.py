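"""Classification performance metrics.

Kept deliberately small: these exact formulas back every reported
performance row, including the balanced-accuracy arithmetic checks.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "balanced_accuracy",
    "sensitivity_specificity",
    "auc_score",
]


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """(sensitivity + specificity) / 2, exactly."""
    return (sensitivity + specificity) / 2.0


def sensitivity_specificity(y_true, y_pred, positive) -> tuple[float, float]:
    """Recall of the positive class and of its complement.

    ``y_true``/``y_pred`` are label arrays; ``positive`` designates the
    class treated as positive, everything else is negative.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("both positive and negative samples are required")
    sens = float(np.mean(y_pred[pos] == positive))
    spec = float(np.mean(y_pred[neg] != positive))
    return sens, spec


def auc_score(y_true, scores, positive) -> float:
    """Area under the ROC curve for one-vs-rest scores."""
    y_bin = (np.asarray(y_true) == positive).astype(int)
    return float(roc_auc_score(y_bin, np.asarray(scores, dtype=float)))
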