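"""Exact permutation machinery for small-sample rank statistics.

With only eight animals per condition, asymptotic p-values for Spearman's
rho and the Mann-Whitney U statistic are unreliable, so both tests are
computed by full enumeration of the permutation null whenever the sample is
small enough to enumerate:

* Spearman: all ``n!`` orderings of one variable for ``n <= 9`` (362,880 at
  the worst).  For untied data the null distribution of rho depends only on
  ``n`` and is cached once; tied data (mid-ranks) get a bespoke enumeration
  because the null then depends on both tie patterns.
* Mann-Whitney: all ``C(n_A + n_B, n_A)`` assignments of the pooled values
  to groups, which handles ties exactly without a normal approximation.

Larger samples fall back to the standard approximations in scipy
(t-approximation for rho, tie-corrected normal for U).
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from math import comb

import numpy as np
from scipy import stats

__all__ = [
    "EXACT_SPEARMAN_N_MAX",
    "EXACT_MANNWHITNEY_GROUP_MAX",
    "spearman_exact",
    "spearman_matrix_exact",
    "mannwhitney_exact",
]

#: Largest n for which Spearman p-values are computed by full enumeration.
EXACT_SPEARMAN_N_MAX = 9

#: Largest per-group n for which Mann-Whitney p-values are enumerated.
EXACT_MANNWHITNEY_GROUP_MAX = 8

_EPS = 1e-12


@lru_cache(maxsize=None)
def _permutation_indices(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) index array."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def standardized_ranks(x) -> np.ndarray | None:
    """Mid-ranks of x, centred and scaled to unit norm.

    Returns None for a constant vector (rank correlation undefined).
    The dot product of two such vectors is Spearman's rho (Pearson on
    mid-ranks).
    """
    r = stats.rankdata(np.asarray(x, dtype=float))
    r -= r.mean()
    norm = np.sqrt((r * r).sum())
    if norm < _EPS:
        return None
    return r / norm


@lru_cache(maxsize=None)
def _untied_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations, for tie-free data."""
    z = standardized_ranks(np.arange(n))
    perms = _permutation_indices(n)
    null = z[perms] @ z
    return np.sort(np.abs(null))


def _exact_p_from_null(null_abs: np.ndarray, abs_obs: float) -> float:
    """P(|rho_perm| >= |rho_obs|) against a sorted |rho| null array."""
    k = null_abs.size - np.searchsorted(null_abs, abs_obs - 1e-9, side="left")
    return k / null_abs.size


def _has_ties(x) -> bool:
    return np.unique(np.asarray(x)).size < np.asarray(x).size


def spearman_exact(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value, exact for n <= 9.

    Returns ``(rho, p)``; ``(nan, nan)`` if either vector is constant.
    Two-sided p is ``P(|rho_perm| >= |rho_obs|)`` over the full permutation
    null, so the smallest attainable p is ``2/n!`` and never zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation requires n >= 3 observations")
    zx = standardized_ranks(x)
    zy = standardized_ranks(y)
    if zx is None or zy is None:
        return float("nan"), float("nan")
    rho = float(zx @ zy)
    if n <= EXACT_SPEARMAN_N_MAX:
        if _has_ties(x) or _has_ties(y):
            perms = _permutation_indices(n)
            null = zx[perms] @ zy
            p = float(np.mean(np.abs(null) >= abs(rho) - 1e-9))
        else:
            p = float(_exact_p_from_null(_untied_null_abs_rho(n), abs(rho)))
    else:
        # t-approximation, the scipy default for large n
        if abs(rho) >= 1.0 - _EPS:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def spearman_matrix_exact(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided p for an (n, R) data matrix.

    Exact permutation p for n <= 9 (shared permutation table across the
    R(R-1)/2 pairs); t-approximation otherwise.  Constant columns give NaN
    in their row/column of both matrices.
    """
    data = np.asarray(data, dtype=float)
    n, n_reg = data.shape
    if n < 4:
        raise ValueError("need n >= 4 subjects")
    rho = np.full((n_reg, n_reg), np.nan)
    pmat = np.full((n_reg, n_reg), np.nan)
    zs = [standardized_ranks(data[:, j]) for j in range(n_reg)]
    tied = [zs[j] is not None and _has_ties(data[:, j]) for j in range(n_reg)]
    exact = n <= EXACT_SPEARMAN_N_MAX
    perms = _permutation_indices(n) if exact else None
    # permuted rank columns, built lazily only where ties force enumeration
    gathered: dict[int, np.ndarray] = {}

    def _gather(j: int) -> np.ndarray:
        if j not in gathered:
            gathered[j] = zs[j][perms]
        return gathered[j]

    for i in range(n_reg):
        if zs[i] is None:
            continue
        rho[i, i] = 1.0
        pmat[i, i] = 0.0
        for j in range(i + 1, n_reg):
            if zs[j] is None:
                continue
            r = float(zs[i] @ zs[j])
            if exact:
                if tied[i] or tied[j]:
                    null = _gather(i) @ zs[j]
                    p = float(np.mean(np.abs(null) >= abs(r) - 1e-9))
                else:
                    p = _exact_p_from_null(_untied_null_abs_rho(n), abs(r))
            else:
                if abs(r) >= 1.0 - _EPS:
                    p = 0.0
                else:
                    t = r * np.sqrt((n - 2) / (1.0 - r * r))
                    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = min(p, 1.0)
    return rho, pmat


@lru_cache(maxsize=None)
def _combination_indices(n_total: int, n_a: int) -> np.ndarray:
    """All C(n_total, n_a) index sets for group A, as an (M, n_a) array."""
    return np.array(
        list(itertools.combinations(range(n_total), n_a)), dtype=np.intp
    )


def mannwhitney_exact(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test, exact by enumeration for small groups.

    Returns ``(U, p)`` where U is the statistic for the first group.  For
    groups of at most ``EXACT_MANNWHITNEY_GROUP_MAX`` the p-value enumerates
    every assignment of the pooled (possibly tied) values to the two groups
    and measures two-sidedness as distance of U from its null mean
    ``n_a n_b / 2`` (the enumeration null is symmetric about that mean).
    Larger groups use scipy's tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    mid = n_a * n_b / 2.0
    if np.unique(pooled).size == 1:
        return u_obs, 1.0
    if max(n_a, n_b) <= EXACT_MANNWHITNEY_GROUP_MAX:
        combs = _combination_indices(n_a + n_b, n_a)
        u_null = ranks[combs].sum(axis=1) - n_a * (n_a + 1) / 2.0
        p = float(
            np.mean(np.abs(u_null - mid) >= abs(u_obs - mid) - 1e-9)
        )
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
    return u_obs, min(p, 1.0)


def n_assignments(n_a: int, n_b: int) -> int:
    """Number of label assignments the exact Mann-Whitney null enumerates."""
    return comb(n_a + n_b, n_a)
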