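"""Independent brute-force oracles used by unit and acceptance tests.

Deliberately naive loop implementations, kept separate from the library's
vectorised code paths.
"""

from __future__ import annotations

import numpy as np


def naive_windowed_average_variance(values, valid, window_size):
    """Loop-based averaged window variance (shrink policy, R-1 denominator)."""
    values = np.asarray(values, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    K = len(values) // window_size
    variances = []
    for k in range(K):
        window = values[k * window_size : (k + 1) * window_size]
        mask = valid[k * window_size : (k + 1) * window_size]
        kept = window[mask]
        if kept.size < 2:
            continue
        mean = kept.sum() / kept.size
        variances.append(((kept - mean) ** 2).sum() / (kept.size - 1))
    if not variances:
        return None
    return sum(variances) / len(variances)


def naive_best_cutpoint(values, positive):
    """Exhaustive candidate x orientation scan maximising the Youden index.

    Returns (best_J, best_cutpoint_for_high_orientation) where the
    cutpoint is the smallest candidate attaining the best J under the
    'positive iff value >= c' rule.
    """
    values = np.asarray(values, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n1 = positive.sum()
    n0 = (~positive).sum()
    best_j_any = -np.inf
    best_j_high = -np.inf
    best_c_high = None
    for c in sorted(set(values)):
        for orientation in (">=", "<"):
            pred = values >= c if orientation == ">=" else values < c
            sens = (pred & positive).sum() / n1
            spec = (~pred & ~positive).sum() / n0
            j = sens + spec - 1.0
            best_j_any = max(best_j_any, j)
            if orientation == ">=" and j > best_j_high:
                best_j_high = j
                best_c_high = c
    return best_j_any, best_j_high, best_c_high


def naive_auc(scores, positive):
    """Pairwise-comparison AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    pos = scores[positive]
    neg = scores[~positive]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
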