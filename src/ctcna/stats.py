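"""Non-parametric tests and multiple-testing helpers shared by the
calling and imbalance stages.

The Mann-Whitney U test is computed by exact tie-aware enumeration when
both groups have at most EXACT_MW_MAX observations (C(16,8) = 12,870
arrangements at worst), and by scipy's normal approximation with tie
correction and continuity correction otherwise. scipy's own exact
method ignores ties, hence the in-package enumeration.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MW_MAX = 8

__all__ = [
    "mann_whitney_p",
    "ks_p",
    "kruskal_wallis_p",
    "hypergeometric_tail",
    "bh_adjust",
]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x vs y, ties counted half."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def exact_mann_whitney_p(x, y) -> float:
    """Two-sided exact MW p by enumerating all C(n+m, n) group assignments
    of the pooled values; valid under ties (permutation null)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mean_u = n * m / 2.0
    dev_obs = abs(u_obs - mean_u)
    total = comb(n + m, n)
    hits = 0
    idx = np.arange(n + m)
    for pick in combinations(idx, n):
        sel = np.zeros(n + m, dtype=bool)
        sel[list(pick)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        if abs(u - mean_u) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value (rank-sum / Wilcoxon)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if len(x) <= EXACT_MW_MAX and len(y) <= EXACT_MW_MAX:
        return exact_mann_whitney_p(x, y)
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def ks_p(x, y) -> float:
    """Two-sample Kolmogorov-Smirnov p-value."""
    return float(sps.ks_2samp(x, y).pvalue)


def kruskal_wallis_p(groups: list[np.ndarray]) -> float:
    return float(sps.kruskal(*groups).pvalue)


def hypergeometric_tail(overlap: int, universe: int, term_size: int, query_size: int) -> float:
    """P[X >= overlap] for X ~ Hypergeom(universe, term_size, query_size)."""
    if overlap <= 0:
        return 1.0
    return float(sps.hypergeom.sf(overlap - 1, universe, term_size, query_size))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
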