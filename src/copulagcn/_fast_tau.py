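"""Numba-compiled pairwise Kendall tau-b for the cell-cell matrix.

Same exact integer pair counts as :func:`copulagcn.copula.kendall_tau`
(Knight's algorithm with tau-b tie corrections), compiled once and applied
to every unordered cell pair.  Falls back to a scipy loop when numba is
unavailable; the test suite pins exact agreement between the routes.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep in practice
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(fn):
            return fn

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=False)
def _tie_term_sorted(v):
    total = 0
    i = 0
    n = v.shape[0]
    while i < n:
        j = i
        while j < n and v[j] == v[i]:
            j += 1
        t = j - i
        total += t * (t - 1) // 2
        i = j
    return total


@njit(cache=False)
def _merge_count_inplace(y, buf):
    """Bottom-up merge sort of y counting inversions (strict)."""
    n = y.shape[0]
    swaps = 0
    width = 1
    while width < n:
        lo = 0
        while lo < n:
            mid = min(lo + width, n)
            hi = min(lo + 2 * width, n)
            if mid < hi:
                i = lo
                j = mid
                k = lo
                while i < mid and j < hi:
                    if y[j] < y[i]:
                        buf[k] = y[j]
                        j += 1
                        swaps += mid - i
                    else:
                        buf[k] = y[i]
                        i += 1
                    k += 1
                while i < mid:
                    buf[k] = y[i]
                    i += 1
                    k += 1
                while j < hi:
                    buf[k] = y[j]
                    j += 1
                    k += 1
                for k2 in range(lo, hi):
                    y[k2] = buf[k2]
            lo += 2 * width
        width *= 2
    return swaps


@njit(cache=False)
def _pair_tau_nb(xs_order, x_sorted, n1_x, y_raw, n2_y, y_buf, merge_buf):
    """tau-b of one pair given precomputations for the first vector.

    xs_order: argsort of x (stable); x_sorted: x in that order; n1_x: x tie
    term; y_raw: second vector (original order); n2_y: its tie term.
    """
    n = x_sorted.shape[0]
    for i in range(n):
        y_buf[i] = y_raw[xs_order[i]]
    # sort y within runs of tied x (insertion sort; runs are short) and
    # accumulate joint (x,y) ties
    joint = 0
    i = 0
    while i < n:
        j = i
        while j < n and x_sorted[j] == x_sorted[i]:
            j += 1
        if j - i > 1:
            for a in range(i + 1, j):
                key = y_buf[a]
                b = a - 1
                while b >= i and y_buf[b] > key:
                    y_buf[b + 1] = y_buf[b]
                    b -= 1
                y_buf[b + 1] = key
            k = i
            while k < j:
                m = k
                while m < j and y_buf[m] == y_buf[k]:
                    m += 1
                t = m - k
                joint += t * (t - 1) // 2
                k = m
        i = j
    swaps = _merge_count_inplace(y_buf, merge_buf)
    n0 = n * (n - 1) // 2
    num = n0 - n1_x - n2_y + joint - 2 * swaps
    d1 = n0 - n1_x
    d2 = n0 - n2_y
    if d1 == 0 or d2 == 0:
        return 0.0
    return num / np.sqrt(d1 * d2)


@njit(cache=False)
def _pairwise_tau_nb(vals):
    n, g = vals.shape
    orders = np.empty((n, g), dtype=np.int64)
    sorted_vals = np.empty((n, g))
    tie_terms = np.empty(n, dtype=np.int64)
    for i in range(n):
        orders[i] = np.argsort(vals[i], kind="mergesort")
        sorted_vals[i] = vals[i][orders[i]]
        tie_terms[i] = _tie_term_sorted(sorted_vals[i])
    out = np.eye(n)
    y_buf = np.empty(g)
    merge_buf = np.empty(g)
    for i in range(n):
        for j in range(i + 1, n):
            t = _pair_tau_nb(
                orders[i], sorted_vals[i], tie_terms[i],
                vals[j], tie_terms[j], y_buf, merge_buf,
            )
            out[i, j] = t
            out[j, i] = t
    return out


def pairwise_tau(vals: np.ndarray) -> np.ndarray:
    """Symmetric matrix of tau-b between all rows of ``vals``."""
    vals = np.ascontiguousarray(vals, dtype=np.float64)
    if HAVE_NUMBA:
        return _pairwise_tau_nb(vals)
    from scipy import stats

    n = vals.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if np.all(vals[i] == vals[i, 0]) or np.all(vals[j] == vals[j, 0]):
                t = 0.0
            else:
                t = stats.kendalltau(vals[i], vals[j], variant="b").statistic
                t = 0.0 if np.isnan(t) else float(t)
            out[i, j] = out[j, i] = t
    return out
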