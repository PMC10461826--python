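"""Numba-compiled sweep kernels.

All kernels operate on rank-compressed integer data prepared by the pure
Python callers in :mod:`gpstest.ecdf`, :mod:`gpstest.statistic` and
:mod:`gpstest.hoeffding`:

``order``
    indices sorted ascending by ``u`` (stable),
``group_starts``
    start offsets of the tied-``u`` batches within ``order`` plus a final
    sentinel ``n``; a whole batch is inserted into the order-statistic
    structure before any of its members is queried, so that ``u_j <= u_i``
    holds for tied ``j``,
``vr``
    per-index "count <=" ranks of ``v`` (equal values share a rank),
``m``
    the largest rank in ``vr``.

The order-statistic structure is a Fenwick (binary indexed) tree over
``v``-ranks, giving O(log n) insertion and prefix-count queries.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def tree_joint_counts(order, group_starts, vr, m):
    """Joint dominance counts: out[i] = #{j : u_j <= u_i and v_j <= v_i}."""
    n = order.size
    counts = np.zeros(n, np.int64)
    tree = np.zeros(m + 1, np.int64)
    for g in range(group_starts.size - 1):
        s = group_starts[g]
        e = group_starts[g + 1]
        for k in range(s, e):
            idx = vr[order[k]]
            while idx <= m:
                tree[idx] += 1
                idx += idx & (-idx)
        for k in range(s, e):
            i = order[k]
            idx = vr[i]
            tot = 0
            while idx > 0:
                tot += tree[idx]
                idx -= idx & (-idx)
            counts[i] = tot
    return counts


@njit(cache=True, fastmath=True)
def sweep_gps_max(order, group_starts, vr, m, cu, scale):
    """Maximum of the weighted ecdf discrepancy over observed points.

    ``cu`` holds the (fixed) marginal "count <=" ranks of ``u`` and ``vr``
    those of the (possibly permuted) ``v``; ``scale = sqrt(n / ln n)``.
    Points with F_u * F_v == 1 (degenerate 0/0 weight) are skipped.
    Returns the running maximum, the fast path of the permutation null.
    """
    n = order.size
    tree = np.zeros(m + 1, np.int32)
    best = 0.0
    n2 = float(n) * float(n)
    for g in range(group_starts.size - 1):
        s = group_starts[g]
        e = group_starts[g + 1]
        for k in range(s, e):
            idx = vr[order[k]]
            while idx <= m:
                tree[idx] += 1
                idx += idx & (-idx)
        for k in range(s, e):
            i = order[k]
            idx = vr[i]
            tot = 0
            while idx > 0:
                tot += tree[idx]
                idx -= idx & (-idx)
            fufv = cu[i] * vr[i] / n2
            if fufv >= 1.0:
                continue
            num = tot / float(n) - fufv
            if num < 0.0:
                num = -num
            t = scale * num / np.sqrt(fufv * (1.0 - fufv))
            if t > best:
                best = t
    return best


@njit(cache=True)
def hoeffding_c(order, group_starts, vr, m):
    """Half-count concordance counts for Hoeffding's D.

    out[i] = #{j != i : u_j < u_i and v_j < v_i}, where a tie in either
    coordinate contributes a factor 1/2 (1/4 when tied in both).
    """
    n = order.size
    c = np.zeros(n, np.float64)
    tree = np.zeros(m + 1, np.int64)
    buf = np.empty(n, np.int64)
    for g in range(group_starts.size - 1):
        s = group_starts[g]
        e = group_starts[g + 1]
        # strictly smaller u: everything already inserted
        for k in range(s, e):
            i = order[k]
            idx = vr[i] - 1
            less = 0
            while idx > 0:
                less += tree[idx]
                idx -= idx & (-idx)
            idx = vr[i]
            upto = 0
            while idx > 0:
                upto += tree[idx]
                idx -= idx & (-idx)
            c[i] = less + 0.5 * (upto - less)
        # tied u within the batch: factor 1/2 on the u coordinate
        gsize = e - s
        if gsize > 1:
            for k in range(gsize):
                buf[k] = vr[order[s + k]]
            gvr = np.sort(buf[:gsize])
            for k in range(s, e):
                i = order[k]
                less = np.searchsorted(gvr, vr[i])
                upto = np.searchsorted(gvr, vr[i], side="right")
                eq = upto - less - 1  # exclude self
                c[i] += 0.5 * (less + 0.5 * eq)
        for k in range(s, e):
            idx = vr[order[k]]
            while idx <= m:
                tree[idx] += 1
                idx += idx & (-idx)
    return c
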