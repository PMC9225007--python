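"""Evaluation metrics.

The accuracy convention throughout is the *Pearson R²*: the square of the
Pearson correlation coefficient between predicted and true values, always
computed on the original (de-standardized) scale.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def pearson_r2(pred: np.ndarray, true: np.ndarray) -> float:
    """Square of the Pearson correlation between prediction and truth.

    Requires equal-length vectors of at least 3 points; constant vectors
    make the correlation undefined and raise a ValueError.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal length")
    if pred.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(pred) == 0 or np.ptp(true) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = stats.pearsonr(pred, true).statistic
    return float(r * r)
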