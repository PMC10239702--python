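"""Shared statistical kernels: BH adjustment and exact 2x2 tests.

BH goes through statsmodels; Fisher's exact test through scipy.  Both are
validated in the test suite against independent enumeration oracles.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (same order as input)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@lru_cache(maxsize=200_000)
def fisher_exact_2x2(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Fisher's exact p for the table [[a, b], [c, d]].

    Cached because cohort-scale occupancy tables repeat heavily (margins are
    the two cohort sizes).
    """
    return float(sps.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def hypergeom_enrichment_p(k: int, M: int, n: int, N: int) -> float:
    """One-sided over-representation p: P(X >= k), X ~ Hypergeom(M, n, N)."""
    return float(sps.hypergeom.sf(k - 1, M, n, N))


def welch_t_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch two-sample t-test; returns (t, p).

    Degenerate rows (zero variance in both groups) get p = 1 when the means
    are equal, p = 0 when they differ.
    """
    res = sps.ttest_ind(x, y, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    diff = x.mean(axis=1) - y.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0)] = 0.0
    t[degenerate] = 0.0
    return t, p


def rank_biserial_from_u(u: float, n1: int, n2: int) -> float:
    """Rank-biserial effect size from a Mann-Whitney U statistic."""
    return 2.0 * u / (n1 * n2) - 1.0
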