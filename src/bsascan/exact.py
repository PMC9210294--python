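"""Vectorized two-sided Fisher's exact test for 2x2 allele-depth tables.

The Monte-Carlo threshold machinery needs exact-test P-values for millions of
simulated tables whose margins (the two bulks' read depths) repeat heavily.
For a fixed depth pair (n1, n2) the P-value of the table
``[[n1-a1, a1], [n2-a2, a2]]`` depends only on the ALT counts (a1, a2), so we
precompute a full (n1+1) x (n2+1) grid per depth pair and cache it.  The
two-sided rule is the classical one (and the one scipy uses): sum the
probabilities of all outcomes on the observed anti-diagonal whose
hypergeometric probability does not exceed the observed one (with a 1e-7
relative tolerance for floating-point ties).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln

_REL_TOL = 1.0 + 1e-7


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@lru_cache(maxsize=None)
def pvalue_grid(n1: int, n2: int) -> np.ndarray:
    """Two-sided Fisher P for every table with bulk depths (n1, n2).

    ``grid[a1, a2]`` is the P-value of ``[[n1-a1, a1], [n2-a2, a2]]``.
    The grid is read-only (cached and shared).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both depths must be >= 1")
    a1 = np.arange(n1 + 1)
    a2 = np.arange(n2 + 1)
    # log P(a1 | K=a1+a2 ALT reads among n1+n2) up to the common K-margin term
    logpmf = (
        _log_binom(n1, a1)[:, None]
        + _log_binom(n2, a2)[None, :]
        - _log_binom(n1 + n2, a1[:, None] + a2[None, :])
    )
    pmf = np.exp(logpmf)
    grid = np.empty_like(pmf)
    for k in range(n1 + n2 + 1):  # anti-diagonal = fixed ALT-column margin
        lo = max(0, k - n2)
        hi = min(n1, k)
        i1 = np.arange(lo, hi + 1)
        i2 = k - i1
        v = pmf[i1, i2]
        order = np.argsort(v, kind="stable")
        cumsum = np.cumsum(v[order])
        rank = np.searchsorted(v[order], v * _REL_TOL, side="right")
        grid[i1, i2] = np.minimum(cumsum[rank - 1], 1.0)
    grid.setflags(write=False)
    return grid


def fisher_pvalues(
    ad_ref1: np.ndarray,
    ad_alt1: np.ndarray,
    ad_ref2: np.ndarray,
    ad_alt2: np.ndarray,
) -> np.ndarray:
    """Two-sided Fisher P-values for arrays of 2x2 allele-depth tables."""
    ad_ref1 = np.asarray(ad_ref1, dtype=np.int64)
    ad_alt1 = np.asarray(ad_alt1, dtype=np.int64)
    ad_ref2 = np.asarray(ad_ref2, dtype=np.int64)
    ad_alt2 = np.asarray(ad_alt2, dtype=np.int64)
    n1 = ad_ref1 + ad_alt1
    n2 = ad_ref2 + ad_alt2
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("every table needs at least one read in each bulk")
    out = np.empty(n1.shape, dtype=float)
    pairs = np.stack([n1.ravel(), n2.ravel()], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    flat_a1 = ad_alt1.ravel()
    flat_a2 = ad_alt2.ravel()
    flat_out = out.ravel()
    for i, (d1, d2) in enumerate(uniq):
        sel = inverse == i
        grid = pvalue_grid(int(d1), int(d2))
        flat_out[sel] = grid[flat_a1[sel], flat_a2[sel]]
    return out


class SignificanceLookup:
    """Fast ``P < alpha`` lookup across a fixed collection of depth pairs.

    Precomputes, for every unique depth pair in the dataset, the boolean grid
    of significant (a1, a2) outcomes, flattened into one array so simulated
    ALT counts can be tested with pure integer indexing.
    """

    def __init__(self, n1: np.ndarray, n2: np.ndarray, alpha: float):
        n1 = np.asarray(n1, dtype=np.int64)
        n2 = np.asarray(n2, dtype=np.int64)
        if np.any(n1 < 1) or np.any(n2 < 1):
            raise ValueError("every SNP needs at least one read in each bulk")
        pairs = np.stack([n1, n2], axis=1)
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        self.n1 = n1
        self.n2 = n2
        self.pair_index = inverse
        widths = uniq[:, 1] + 1
        sizes = (uniq[:, 0] + 1) * widths
        offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        flat = np.empty(int(sizes.sum()), dtype=bool)
        for i, (d1, d2) in enumerate(uniq):
            g = pvalue_grid(int(d1), int(d2)) < alpha
            flat[offsets[i] : offsets[i] + sizes[i]] = g.ravel()
        self._flat = flat
        self._offsets = offsets
        self._widths = widths

    def significant(self, snp_idx: np.ndarray, a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
        """Significance of simulated ALT counts for the SNPs at ``snp_idx``."""
        pid = self.pair_index[snp_idx]
        return self._flat[self._offsets[pid] + a1 * self._widths[pid] + a2]
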