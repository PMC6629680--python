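"""Published reference operating points for the binary classifiers.

These rows reproduce the reference study's reported per-task AUC,
sensitivity and specificity for cyst fluid and plasma.  They are used
as fixed inputs for metric-arithmetic regression checks (the balanced
accuracy column must equal ``(sensitivity + specificity) / 2`` as
computed by :mod:`cystomics.metrics`), never as expected outputs of any
simulation.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_performance"]

_ROWS = [
    # task, fluid, auc, sensitivity, specificity, balanced_accuracy
    ("SCN vs All", "cyst", 1.000, 1.000, 1.000, 1.000),
    ("SCN vs All", "plasma", 0.950, 0.800, 0.875, 0.837),
    ("LGD vs All", "cyst", 0.935, 0.875, 0.913, 0.894),
    ("LGD vs All", "plasma", 0.825, 1.000, 0.812, 0.906),
    ("HGD-Cancer vs All", "cyst", 0.949, 0.889, 0.923, 0.906),
    ("HGD-Cancer vs All", "plasma", 0.854, 0.636, 1.000, 0.818),
    ("IPMN vs SCN", "cyst", 1.000, 1.000, 1.000, 1.000),
    ("IPMN vs SCN", "plasma", 1.000, 1.000, 1.000, 1.000),
]


def reference_performance() -> pd.DataFrame:
    """Reference per-task performance table (one row per task x fluid)."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "task",
            "fluid",
            "auc",
            "sensitivity",
            "specificity",
            "balanced_accuracy",
        ],
    )
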