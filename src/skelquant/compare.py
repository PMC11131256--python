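"""Group comparison of the 11 descriptors (mean ± SD and t-test).

Each descriptor is compared between the ADHD and non-ADHD groups with a
two-sample t-test.  Welch's unequal-variance form is the default: the
two groups' descriptor SDs differ by factors up to ~5, which violates the
pooled-variance assumption; the classical pooled test is available by
flag.  No multiplicity adjustment is applied across the 11 tests — each
descriptor is reported marginally, as is conventional for this kind of
per-feature screening table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .features import DESCRIPTORS, DESCRIPTOR_TITLES, LABEL_COLUMN
from .skeleton import ADHD

__all__ = ["significance_stars", "compare_groups"]

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Stars for a p-value: * <0.05, ** <0.01, *** <0.001."""
    if np.isnan(p):
        return ""
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


def compare_groups(dataset: pd.DataFrame, equal_var: bool = False) -> pd.DataFrame:
    """Per-descriptor group means, SDs and two-sided t-test p-values.

    Returns one row per descriptor with columns ``adhd_mean``, ``adhd_sd``,
    ``non_adhd_mean``, ``non_adhd_sd``, ``t``, ``p_value``, ``stars`` and a
    ``degenerate`` flag raised when both groups have zero variance (the
    test statistic is then undefined and ``p_value`` is NaN).
    """
    is_adhd = dataset[LABEL_COLUMN] == ADHD
    if is_adhd.sum() < 2 or (~is_adhd).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    rows = []
    for descriptor in DESCRIPTORS:
        a = dataset.loc[is_adhd, descriptor].to_numpy(dtype=float)
        b = dataset.loc[~is_adhd, descriptor].to_numpy(dtype=float)
        degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
        if degenerate:
            t_stat, p = np.nan, np.nan
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "feature": descriptor,
                "title": DESCRIPTOR_TITLES[descriptor],
                "adhd_mean": a.mean(),
                "adhd_sd": a.std(ddof=1),
                "non_adhd_mean": b.mean(),
                "non_adhd_sd": b.std(ddof=1),
                "t": float(t_stat),
                "p_value": float(p),
                "stars": significance_stars(float(p)),
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
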