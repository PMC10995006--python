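"""Rank-based statistical comparison of classification models.

Paired Wilcoxon signed-rank for model-vs-baseline contrasts, the Friedman
test across many models evaluated on the same folds, and the Nemenyi
post-hoc critical difference used to group models for critical-difference
diagrams.

Rank orientation: within each fold, models are ranked by accuracy with
rank 1 for the worst and rank k for the best (ties get average ranks), so
low mean ranks mean low accuracy.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

# Two-tailed studentized-range constants q_alpha / sqrt(2) for the Nemenyi
# test, k = 2..10 models, as tabulated by Demsar (2006), JMLR 7:1-30.
NEMENYI_Q: Dict[float, Dict[int, float]] = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
           7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589,
           7: 2.693, 8: 2.780, 9: 2.855, 10: 2.920},
}


def wilcoxon_signed(per_fold_a, per_fold_b) -> Tuple[float, float]:
    """Two-tailed paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's convention). If every
    difference is zero there is no evidence of a difference and p = 1 is
    returned with a warning. The exact null distribution is used whenever
    scipy can compute it (small n, no rank ties), otherwise the normal
    approximation.
    """
    a = np.asarray(per_fold_a, dtype=float)
    b = np.asarray(per_fold_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need paired samples of equal length >= 5")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; no evidence of difference")
        return 0.0, 1.0
    n_nonzero = int(np.count_nonzero(d))
    method = "exact" if n_nonzero <= 25 else "approx"
    try:
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    except (ValueError, TypeError):
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method="approx")
    return float(res.statistic), float(res.pvalue)


def shapiro_normality(values) -> Tuple[float, float]:
    """Shapiro-Wilk normality check, reported and logged (never branching)."""
    w, p = stats.shapiro(np.asarray(values, dtype=float))
    logger.info("Shapiro-Wilk W=%.4f p=%.4g", w, p)
    return float(w), float(p)


def _as_matrix(accuracy_matrix) -> Tuple[np.ndarray, List[str]]:
    if isinstance(accuracy_matrix, pd.DataFrame):
        return accuracy_matrix.to_numpy(dtype=float), [str(c) for c in accuracy_matrix.columns]
    m = np.asarray(accuracy_matrix, dtype=float)
    return m, [f"model{j}" for j in range(m.shape[1])]


def friedman_test(accuracy_matrix) -> Tuple[float, int, float]:
    """Tie-corrected Friedman chi-squared test across models.

    Models are ranked within each fold (average ranks for ties); the
    classic chi-squared statistic is divided by the tie-correction factor
    and referred to a chi-squared distribution with k-1 degrees of
    freedom. A fully tied matrix yields (0, df, 1) by convention.
    """
    m, _ = _as_matrix(accuracy_matrix)
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 folds and 2 models")
    ranks = rankdata(m, axis=1)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # Tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1)).
    tie_term = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    df = k - 1
    if correction <= 0:
        return 0.0, df, 1.0
    statistic = chi2 / correction
    return float(statistic), df, float(stats.chi2.sf(statistic, df))


def nemenyi_critical_difference(
    n_models: int, n_folds: int, alpha: float = 0.05
) -> float:
    """Critical mean-rank difference CD = q_alpha * sqrt(k(k+1)/(6N))."""
    if alpha not in NEMENYI_Q:
        raise ValueError(f"alpha must be one of {sorted(NEMENYI_Q)}")
    table = NEMENYI_Q[alpha]
    if n_models not in table:
        raise ValueError(
            f"n_models={n_models} outside the tabulated range "
            f"{min(table)}..{max(table)}"
        )
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    return table[n_models] * math.sqrt(n_models * (n_models + 1) / (6.0 * n_folds))


@dataclass
class ComparisonResult:
    """Friedman test + Nemenyi grouping over a folds x models matrix."""

    statistic: float
    df: int
    p_value: float
    mean_ranks: pd.Series  # model -> mean rank (k = best)
    critical_difference: float
    groups: List[Tuple[str, ...]]  # models not significantly different
    alpha: float

    def to_dict(self) -> Dict:
        return {
            "friedman_statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "mean_ranks": {str(k): float(v) for k, v in self.mean_ranks.items()},
            "critical_difference": self.critical_difference,
            "groups": [list(g) for g in self.groups],
            "alpha": self.alpha,
        }


def rank_and_group(accuracy_matrix, alpha: float = 0.05) -> ComparisonResult:
    """Mean ranks, Friedman test, and Nemenyi grouping of models.

    Two models whose mean-rank difference is below the critical difference
    are not significantly different; the emitted groups are the maximal
    sets of rank-consecutive models whose rank span is below CD (the
    horizontal bars of a critical-difference diagram). Every model belongs
    to at least one group.
    """
    m, names = _as_matrix(accuracy_matrix)
    statistic, df, p = friedman_test(m)
    ranks = rankdata(m, axis=1)
    mean_ranks = pd.Series(ranks.mean(axis=0), index=names)
    cd = nemenyi_critical_difference(m.shape[1], m.shape[0], alpha)

    order = mean_ranks.sort_values().index.to_list()
    sorted_ranks = mean_ranks[order].to_numpy()
    groups: List[Tuple[str, ...]] = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and sorted_ranks[j + 1] - sorted_ranks[i] < cd:
            j += 1
        group = tuple(order[i : j + 1])
        if not any(set(group) <= set(g) for g in groups):
            groups.append(group)
    return ComparisonResult(
        statistic=statistic,
        df=df,
        p_value=p,
        mean_ranks=mean_ranks,
        critical_difference=cd,
        groups=groups,
        alpha=alpha,
    )
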