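"""Classical univariate statistics for whole-profile comparisons.

The analysis unit is the whole soil profile (stocks summed over depth
increments, concentrations mass-weighted), three replicate pits per
land-use class.  Provided: one-way ANOVA with Tukey HSD post-hoc
comparisons (Tukey-Kramer for unequal group sizes), Spearman rank
correlation, Pearson correlation with a t-based p value, and ordinary
least-squares line fits with r^2.  Computation is delegated to
scipy.stats and statsmodels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DomainError, InsufficientDataError


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise results."""

    groups: tuple[str, ...]
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # group1, group2, diff, lower, upper, p_adj, reject
    alpha: float


def anova_tukey(values, groups, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA followed by a Tukey HSD post-hoc test.

    Requires at least two groups with at least two observations each.
    Pairwise intervals use the studentized range with the Tukey-Kramer
    harmonic-mean adjustment for unequal group sizes.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise DomainError("values and groups must have equal length")
    labels = tuple(dict.fromkeys(g.tolist()))
    if len(labels) < 2:
        raise InsufficientDataError("need at least 2 groups")
    samples = [v[g == lab] for lab in labels]
    for lab, s in zip(labels, samples):
        if len(s) < 2:
            raise InsufficientDataError(
                f"group {lab!r} has fewer than 2 observations"
            )
    f_stat, p = stats.f_oneway(*samples)
    if not np.isfinite(f_stat):
        # degenerate decompositions: no between-group spread means F = 0
        # even when the within-group variance is also zero
        grand = v.mean()
        ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        if ss_between <= 1e-12 * max(1.0, grand ** 2):
            f_stat, p = 0.0, 1.0
        elif ss_within == 0.0:
            f_stat, p = np.inf, 0.0
    hsd = pairwise_tukeyhsd(v, g, alpha=alpha)
    pairs = list(itertools.combinations(hsd.groupsunique, 2))
    tukey = pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "diff": hsd.meandiffs,
        "lower": hsd.confint[:, 0],
        "upper": hsd.confint[:, 1],
        "p_adj": hsd.pvalues,
        "reject": hsd.reject,
    })
    expected = len(labels) * (len(labels) - 1) // 2
    assert len(tukey) == expected
    return GroupComparison(
        groups=labels, f_statistic=float(f_stat), p_value=float(p),
        tukey=tukey, alpha=alpha,
    )


def _check_pair(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-d arrays")
    if len(x) < min_n:
        raise InsufficientDataError(f"need at least {min_n} observations")
    return x, y


def rank_correlation(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x, y = _check_pair(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation and two-sided t-based p value."""
    x, y = _check_pair(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def linear_fit_r2(x, y) -> tuple[float, float, float]:
    """Least-squares line fit: (slope, intercept, r^2)."""
    x, y = _check_pair(x, y, 3)
    if np.ptp(x) == 0:
        raise DomainError("degenerate fit: x is constant")
    if np.ptp(y) == 0:
        # a constant response is fit exactly by its mean; no variance explained
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
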