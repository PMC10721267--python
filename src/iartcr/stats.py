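"""Shared statistical utilities: BH-FDR adjustment and permutation Spearman tests.

Rank correlations in this package are tested by permutation rather than by
the asymptotic t approximation because the cohorts involved are small
(7-11 participants per treatment arm). For n at or below ``exact_max_n`` the
permutation distribution is enumerated exhaustively; above that a seeded
Monte Carlo sample of permutations is used with the add-one correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "spearman_perm", "SpearmanPermResult"]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Returns q-values in the input order, with the usual monotonicity
    enforcement. Raises ``ValueError`` for p-values outside [0, 1]
    (including NaN); callers that may produce undefined p-values must
    filter them out first.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class SpearmanPermResult:
    rho: float
    p: float
    n: int
    method: str  # "exact", "monte_carlo" or "degenerate"
    n_permutations: int


_PERM_CACHE: dict[int, np.ndarray] = {}


def _all_permutations(n: int) -> np.ndarray:
    """All n! index permutations as an (n!, n) int8 array (cached)."""
    if n not in _PERM_CACHE:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.int8)
        _PERM_CACHE[n] = perms
    return _PERM_CACHE[n]


def spearman_perm(
    x,
    y,
    n_permutations: int = 10_000,
    seed=None,
    exact_max_n: int = 10,
) -> SpearmanPermResult:
    """Spearman rank correlation with a permutation p-value (two-sided).

    Ties are handled by mid-ranking; rho is the Pearson correlation of the
    rank vectors. If either variable is constant the correlation is
    undefined and NaN is returned with method ``"degenerate"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return SpearmanPermResult(np.nan, np.nan, n, "degenerate", 0)

    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    rho = float(rxc @ ryc / denom)
    eps = 1e-12

    if n <= exact_max_n:
        perms = _all_permutations(n)
        n_perm = perms.shape[0]
        hits = 0
        # chunked so the 10! case stays within a modest memory footprint
        for start in range(0, n_perm, 250_000):
            block = perms[start : start + 250_000]
            stat = ryc[block] @ rxc / denom
            hits += int(np.count_nonzero(np.abs(stat) >= abs(rho) - eps))
        return SpearmanPermResult(rho, hits / n_perm, n, "exact", n_perm)

    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    stat = ryc[idx] @ rxc / denom
    hits = int(np.count_nonzero(np.abs(stat) >= abs(rho) - eps))
    p = (1 + hits) / (1 + n_permutations)
    return SpearmanPermResult(rho, p, n, "monte_carlo", n_permutations)
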