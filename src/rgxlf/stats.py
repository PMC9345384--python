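"""Convenience group-comparison statistics for lung-function readouts.

Thin wrappers over scipy.stats for the two tests typically reported when
comparing k-values or heart rates between cohorts (e.g. dystrophic vs
wild-type mice): Pearson correlation between two paired measurement methods
and the Mann-Whitney U test between two independent groups.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _stats

__all__ = ["pearson_r", "mann_whitney_u"]


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient and two-sided p-value."""
    r = _stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r.statistic), float(r.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U statistic (of the first sample) and two-sided p-value.

    Fully separated groups with every x below every y give U = 0.
    """
    res = _stats.mannwhitneyu(
        np.asarray(x, float), np.asarray(y, float), alternative="two-sided"
    )
    return float(res.statistic), float(res.pvalue)
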