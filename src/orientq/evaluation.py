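"""Evaluation helpers for synthetic-recovery studies."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .factors import FlagMatrix
from .synthetic import GroundTruth


def match_factors_to_types(
    flags: FlagMatrix, truth: GroundTruth, institution_ids: list[str]
) -> tuple[np.ndarray, float]:
    """Best one-to-one matching of factors to planted types.

    Returns the overlap matrix (factors x types: defining sorts of each
    factor belonging to each type) and the fraction of all institutions
    that are defining on the factor matched to their true type (the
    Hungarian assignment maximizing total overlap).  Unflagged
    institutions count as mismatches.
    """
    labels = np.array([truth.labels[i] for i in institution_ids])
    n_types = len(truth.type_names)
    k = flags.flags.shape[1]
    overlap = np.zeros((k, n_types))
    for f in range(k):
        for t in range(n_types):
            overlap[f, t] = np.sum(flags.flags[:, f] & (labels == t))
    rows, cols = linear_sum_assignment(-overlap)
    matched = overlap[rows, cols].sum()
    return overlap, float(matched / len(labels))
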