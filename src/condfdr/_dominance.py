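"""Bivariate dominance counting for the empirical cFDR estimator.

For every observed pair (p_i[k], p_j[k]) we need the joint count

    N_ij[k] = #{m : p_i[m] <= p_i[k] and p_j[m] <= p_j[k]}

with ties counted inclusively on both axes, so each point dominates
itself and N_ij >= 1 everywhere.  A naive double loop is O(n^2); at the
10^5-10^6 SNPs of a genome-wide panel that is prohibitive, so points are
swept in order of increasing p_i while p_j ranks are accumulated in a
Fenwick (binary indexed) tree, giving O(n log n).  Groups of tied p_i
are inserted before any member of the group is queried so that the
"<=" semantics hold exactly.

The sweep is JIT-compiled with numba when available; a pure-Python
fallback with identical semantics is used otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["joint_dominance_counts"]


def _fenwick_sweep_py(rj_sorted, group_ids, m):
    tree = np.zeros(m + 1, dtype=np.int64)
    n = rj_sorted.shape[0]
    out = np.empty(n, dtype=np.int64)
    start = 0
    while start < n:
        end = start
        while end < n and group_ids[end] == group_ids[start]:
            end += 1
        for k in range(start, end):
            i = rj_sorted[k] + 1
            while i <= m:
                tree[i] += 1
                i += i & (-i)
        for k in range(start, end):
            i = rj_sorted[k] + 1
            s = 0
            while i > 0:
                s += tree[i]
                i -= i & (-i)
            out[k] = s
        start = end
    return out


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _fenwick_sweep = njit(cache=True)(_fenwick_sweep_py)
except ImportError:  # pragma: no cover
    _fenwick_sweep = _fenwick_sweep_py


def joint_dominance_counts(p_i: np.ndarray, p_j: np.ndarray) -> np.ndarray:
    """Count, for each point, how many points it dominates (inclusively).

    Parameters
    ----------
    p_i, p_j
        Paired value vectors of equal length.

    Returns
    -------
    numpy.ndarray of int64
        ``out[k] = #{m : p_i[m] <= p_i[k] and p_j[m] <= p_j[k]}``.
    """
    p_i = np.asarray(p_i, dtype=np.float64)
    p_j = np.asarray(p_j, dtype=np.float64)
    if p_i.shape != p_j.shape or p_i.ndim != 1:
        raise ValueError("p_i and p_j must be 1-D arrays of equal length")
    n = p_i.shape[0]
    if n == 0:
        return np.empty(0, dtype=np.int64)

    order = np.argsort(p_i, kind="mergesort")
    pi_sorted = p_i[order]
    # dense group ids over tied p_i so a whole tie group is inserted
    # before its members are queried
    group_ids = np.empty(n, dtype=np.int64)
    group_ids[0] = 0
    np.cumsum(pi_sorted[1:] != pi_sorted[:-1], out=group_ids[1:])

    uniq_j = np.unique(p_j)
    rj = np.searchsorted(uniq_j, p_j)  # dense 0-based rank of p_j
    counts_sorted = _fenwick_sweep(
        rj[order].astype(np.int64), group_ids, int(uniq_j.shape[0])
    )
    out = np.empty(n, dtype=np.int64)
    out[order] = counts_sorted
    return out
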