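"""Scoring primitives shared by the model and evaluation layers."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .containers import labels_to_int


def auc(labels, scores) -> float:
    """ROC area via the Mann-Whitney rank formulation, ties counted 1/2.

    Equals the probability that a randomly chosen positive outscores a
    randomly chosen negative (with ties contributing half), which is the
    area under the ROC curve.
    """
    y = labels_to_int(np.asarray(labels))
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have the same length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    r = rankdata(s)  # average ranks handle ties
    u = r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
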