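"""Associations between gene expression and clinicopathological variables.

Binary variables (ER status) are tested with the Mann–Whitney U test; the
ordinal grade is tested with Spearman rank association of expression versus
the ordinal codes. Missing clinical values are dropped per test
(complete-case) with logged counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_config import logger
from .seedclust import spearman

EXACT_MAX_N = 8


@dataclass
class AssocResult:
    """One association test: statistic, two-sided p, n used and the
    direction (which category has the higher expression)."""

    variable: str
    statistic: float
    p: float
    n: int
    direction: str

    @property
    def stars(self) -> str:
        """Display significance: * p<0.05, ** p<0.01, *** p<0.001."""
        for cut, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p < cut:
                return mark
        return ""


def mann_whitney(values, group, variable: str = "group") -> AssocResult:
    """Mann–Whitney U of *values* between the two levels of *group*.

    Exact two-sided p when both groups have <= 8 observations, otherwise
    the tie-corrected normal approximation.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group, dtype=object)
    ok = ~np.isnan(values) & np.array([g is not None and g == g for g in group])
    values, group = values[ok], group[ok]
    levels = sorted(set(group))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group levels, got {levels}")
    a = values[group == levels[0]]
    b = values[group == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one group is empty")
    method = "exact" if max(len(a), len(b)) <= EXACT_MAX_N else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = str(levels[0]) if np.median(a) > np.median(b) else str(levels[1])
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("mann_whitney(%s): dropped %d incomplete rows", variable, n_dropped)
    return AssocResult(variable=variable, statistic=float(res.statistic),
                       p=float(min(res.pvalue, 1.0)), n=len(a) + len(b), direction=direction)


def spearman_trend(values, ordinal, variable: str = "grade") -> AssocResult:
    """Spearman rank association of expression with an ordinal variable."""
    values = np.asarray(values, dtype=float)
    ordinal = np.asarray(ordinal, dtype=float)
    ok = ~(np.isnan(values) | np.isnan(ordinal))
    v, o = values[ok], ordinal[ok]
    if len(np.unique(o)) < 2:
        raise ValueError("ordinal variable has a single level")
    rho, p = spearman(v, o)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("spearman_trend(%s): dropped %d incomplete rows", variable, n_dropped)
    return AssocResult(variable=variable, statistic=rho, p=p, n=len(v),
                       direction="increasing" if rho >= 0 else "decreasing")
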