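"""Marginal and bivariate empirical distribution functions.

All ecdfs use the "count <=" (maximal-rank) convention: tied values receive
equal, maximal ecdf values. Values are computed as integer counts and
divided by ``n`` at the last moment, so the three bivariate backends agree
bitwise on the rationals ``rank / n``.

Three interchangeable bivariate backends are provided:

``naive``
    two nested loops (vectorised in blocks), O(n^2); the ground-truth
    oracle for the others,
``tree``
    an order-statistic (Fenwick) tree sweep, O(n log n); the default,
``dac``
    divide-and-conquer merge counting of dominated points across halves,
    O(n log^2 n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import InputValidationError
from .pair import HarmonizedPair, validate_pvalues

BACKENDS = ("naive", "tree", "dac")


@dataclass
class EcdfProfile:
    """Per-point marginal and joint ecdf values for a pair of vectors."""

    F_u: np.ndarray
    F_v: np.ndarray
    F_uv: np.ndarray
    backend_name: str


def marginal_counts(values: np.ndarray) -> np.ndarray:
    """Integer counts c[i] = #{j : values[j] <= values[i]}."""
    arr = validate_pvalues(values)
    order = np.sort(arr)
    return np.searchsorted(order, arr, side="right").astype(np.int64)


def marginal_ecdf(values: np.ndarray) -> np.ndarray:
    """Marginal ecdf: out[i] = #{j : values[j] <= values[i]} / n."""
    counts = marginal_counts(values)
    return counts / counts.size


def _check_lengths(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = validate_pvalues(u, "u")
    v = validate_pvalues(v, "v")
    if u.size != v.size:
        raise InputValidationError(
            f"length mismatch: u has {u.size} entries, v has {v.size}"
        )
    return u, v


def _sweep_inputs(u: np.ndarray, v: np.ndarray):
    """Rank-compress for the sweep kernels.

    Returns (order of u, tie-group start offsets, v ranks, max v rank).
    """
    order = np.argsort(u, kind="stable").astype(np.int64)
    us = u[order]
    starts = np.flatnonzero(np.r_[True, us[1:] != us[:-1]])
    group_starts = np.append(starts, u.size).astype(np.int64)
    vs = np.sort(v)
    vr = np.searchsorted(vs, v, side="right").astype(np.int64)
    return order, group_starts, vr, int(vr.max(initial=1))


def bivariate_counts_naive(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Joint counts c[i] = #{j : u_j <= u_i and v_j <= v_i}, O(n^2).

    Blocked broadcasting keeps memory bounded for large n; this backend is
    the oracle the fast backends are verified against.
    """
    u, v = _check_lengths(u, v)
    n = u.size
    counts = np.empty(n, dtype=np.int64)
    block = max(1, 2**24 // max(n, 1))
    for s in range(0, n, block):
        e = min(n, s + block)
        dom = (u[None, :] <= u[s:e, None]) & (v[None, :] <= v[s:e, None])
        counts[s:e] = dom.sum(axis=1)
    return counts


def bivariate_counts_tree(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Joint counts via an order-statistic tree sweep, O(n log n).

    Points are swept in order of ``u``; each tied-``u`` batch is inserted
    into a Fenwick tree over ``v``-ranks before any of its members is
    queried, so the "<=" convention holds exactly under ties.
    """
    u, v = _check_lengths(u, v)
    order, group_starts, vr, m = _sweep_inputs(u, v)
    return _kernels.tree_joint_counts(order, group_starts, vr, m)


def bivariate_counts_dac(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Joint counts via divide and conquer on ``u``, O(n log^2 n).

    The split is on a *value* boundary of ``u`` so that a tie batch never
    straddles the two halves; the cross step counts, for each point in the
    high half, the low-half points it dominates in ``v`` via binary search.
    """
    u, v = _check_lengths(u, v)
    n = u.size
    counts = np.zeros(n, dtype=np.int64)
    order = np.argsort(u, kind="stable")

    def solve(idx: np.ndarray) -> None:
        m = idx.size
        if m == 0:
            return
        uu = u[idx]
        uniq = np.unique(uu)
        if uniq.size == 1:
            # all u tied: 1-d problem on v alone
            vv = np.sort(v[idx])
            counts[idx] += np.searchsorted(vv, v[idx], side="right")
            return
        pivot = uniq[uniq.size // 2]
        lo = idx[uu < pivot]
        hi = idx[uu >= pivot]
        solve(lo)
        solve(hi)
        vlo = np.sort(v[lo])
        counts[hi] += np.searchsorted(vlo, v[hi], side="right")

    solve(order)
    return counts


_COUNT_BACKENDS = {
    "naive": bivariate_counts_naive,
    "tree": bivariate_counts_tree,
    "dac": bivariate_counts_dac,
}


def bivariate_counts(u, v, backend: str = "tree") -> np.ndarray:
    """Joint dominance counts with a selectable backend."""
    try:
        fn = _COUNT_BACKENDS[backend]
    except KeyError:
        raise InputValidationError(
            f"unknown backend {backend!r}; expected one of {BACKENDS}"
        ) from None
    return fn(np.asarray(u, dtype=np.float64), np.asarray(v, dtype=np.float64))


def bivariate_ecdf_naive(u, v) -> np.ndarray:
    """Joint ecdf F_uv[i] = #{j : u_j <= u_i and v_j <= v_i} / n."""
    c = bivariate_counts_naive(np.asarray(u, float), np.asarray(v, float))
    return c / c.size


def bivariate_ecdf_tree(u, v) -> np.ndarray:
    """Joint ecdf via the order-statistic tree backend."""
    c = bivariate_counts_tree(np.asarray(u, float), np.asarray(v, float))
    return c / c.size


def bivariate_ecdf_dac(u, v) -> np.ndarray:
    """Joint ecdf via the divide-and-conquer backend."""
    c = bivariate_counts_dac(np.asarray(u, float), np.asarray(v, float))
    return c / c.size


def ecdf_profile(pair: HarmonizedPair, backend: str = "tree") -> EcdfProfile:
    """Marginal and joint ecdf values for a harmonised pair."""
    F_u = marginal_ecdf(pair.u)
    F_v = marginal_ecdf(pair.v)
    F_uv = bivariate_counts(pair.u, pair.v, backend=backend) / pair.n
    return EcdfProfile(F_u=F_u, F_v=F_v, F_uv=F_uv, backend_name=backend)
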