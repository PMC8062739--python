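"""Nearest-neighbor counting kernels for the KSG conditional MI estimator.

Two interchangeable implementations of the neighbor statistics:

* :func:`cmi_counts_tree` — kd-tree based (scipy), the reference.
* :func:`cmi_counts_sweep` — a numba kernel that sorts points along the
  first conditioning coordinate and sweeps outward, pruning candidates
  whose distance along that coordinate already exceeds the current
  search radius.  All three marginal spaces of the conditional MI
  contain the conditioning variable, so a single sorted order serves
  the neighbor search and all range counts.

Both return, for every point, the k-th nearest-neighbor Chebyshev
distance in the joint space and the strict (< eps) neighbor counts in
the (a, c), (b, c) and (c) marginal spaces; they agree exactly and are
cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

__all__ = ["cmi_counts_tree", "cmi_counts_sweep"]


def cmi_counts_tree(a: np.ndarray, b: np.ndarray, c: np.ndarray, k: int):
    """Neighbor statistics via kd-trees (reference implementation)."""
    joint = np.hstack([a, b, c])
    eps = cKDTree(joint).query(joint, k=k + 1, p=np.inf)[0][:, -1]
    r = np.nextafter(eps, 0)
    ac = np.hstack([a, c])
    bc = np.hstack([b, c])
    n_ac = cKDTree(ac).query_ball_point(ac, r, p=np.inf, return_length=True) - 1
    n_bc = cKDTree(bc).query_ball_point(bc, r, p=np.inf, return_length=True) - 1
    n_c = cKDTree(c).query_ball_point(c, r, p=np.inf, return_length=True) - 1
    return eps, n_ac, n_bc, n_c


@njit(fastmath=False)
def _sweep_kernel(a, b, c, k):          # pragma: no cover - exercised via wrapper
    n = a.shape[0]
    da, db, dc = a.shape[1], b.shape[1], c.shape[1]
    eps_out = np.empty(n)
    n_ac = np.zeros(n, dtype=np.int64)
    n_bc = np.zeros(n, dtype=np.int64)
    n_c = np.zeros(n, dtype=np.int64)
    best = np.empty(k)
    for i in range(n):
        # --- k nearest neighbors in the joint space, sweeping on c[:, 0]
        for m in range(k):
            best[m] = np.inf
        worst = np.inf
        left = i - 1
        right = i + 1
        while left >= 0 or right < n:
            take_left = False
            if left >= 0 and right < n:
                take_left = (c[i, 0] - c[left, 0]) <= (c[right, 0] - c[i, 0])
            elif left >= 0:
                take_left = True
            j = left if take_left else right
            gap = c[i, 0] - c[j, 0] if take_left else c[j, 0] - c[i, 0]
            if gap >= worst:
                if take_left:
                    left = -1
                else:
                    right = n
                continue
            # Chebyshev distance in the joint space with early exit
            d = gap
            for m in range(dc - 1):
                v = abs(c[i, m + 1] - c[j, m + 1])
                if v > d:
                    d = v
                if d >= worst:
                    break
            if d < worst:
                for m in range(da):
                    v = abs(a[i, m] - a[j, m])
                    if v > d:
                        d = v
                    if d >= worst:
                        break
            if d < worst:
                for m in range(db):
                    v = abs(b[i, m] - b[j, m])
                    if v > d:
                        d = v
                    if d >= worst:
                        break
            if d < worst:
                # insert into sorted best list
                pos = k - 1
                while pos > 0 and best[pos - 1] > d:
                    best[pos] = best[pos - 1]
                    pos -= 1
                best[pos] = d
                worst = best[k - 1]
            if take_left:
                left -= 1
            else:
                right += 1
        eps = worst
        eps_out[i] = eps
        # --- strict neighbor counts (< eps) in the marginal spaces
        cac = 0
        cbc = 0
        cc = 0
        left = i - 1
        right = i + 1
        while left >= 0 or right < n:
            take_left = False
            if left >= 0 and right < n:
                take_left = (c[i, 0] - c[left, 0]) <= (c[right, 0] - c[i, 0])
            elif left >= 0:
                take_left = True
            j = left if take_left else right
            gap = c[i, 0] - c[j, 0] if take_left else c[j, 0] - c[i, 0]
            if gap >= eps:
                if take_left:
                    left = -1
                else:
                    right = n
                continue
            dcm = gap
            for m in range(dc - 1):
                v = abs(c[i, m + 1] - c[j, m + 1])
                if v > dcm:
                    dcm = v
                if dcm >= eps:
                    break
            if dcm < eps:
                cc += 1
                dam = dcm
                for m in range(da):
                    v = abs(a[i, m] - a[j, m])
                    if v > dam:
                        dam = v
                    if dam >= eps:
                        break
                if dam < eps:
                    cac += 1
                dbm = dcm
                for m in range(db):
                    v = abs(b[i, m] - b[j, m])
                    if v > dbm:
                        dbm = v
                    if dbm >= eps:
                        break
                if dbm < eps:
                    cbc += 1
            if take_left:
                left -= 1
            else:
                right += 1
        n_ac[i] = cac
        n_bc[i] = cbc
        n_c[i] = cc
    return eps_out, n_ac, n_bc, n_c


@njit(fastmath=False)
def _sweep_kernel_1d(a, b, c, k):       # pragma: no cover - exercised via wrapper
    """Specialization for scalar a, b, c (dim-1 embeddings)."""
    n = a.shape[0]
    eps_out = np.empty(n)
    n_ac = np.zeros(n, dtype=np.int64)
    n_bc = np.zeros(n, dtype=np.int64)
    n_c = np.zeros(n, dtype=np.int64)
    best = np.empty(k)
    for i in range(n):
        ai = a[i]
        bi = b[i]
        ci = c[i]
        for m in range(k):
            best[m] = np.inf
        worst = np.inf
        left = i - 1
        right = i + 1
        while left >= 0 or right < n:
            if left >= 0 and (right >= n or ci - c[left] <= c[right] - ci):
                j = left
                gap = ci - c[j]
                left -= 1
                from_left = True
            else:
                j = right
                gap = c[j] - ci
                right += 1
                from_left = False
            if gap >= worst:
                if from_left:
                    left = -1
                else:
                    right = n
                continue
            d = gap
            v = abs(ai - a[j])
            if v > d:
                d = v
            v = abs(bi - b[j])
            if v > d:
                d = v
            if d < worst:
                pos = k - 1
                while pos > 0 and best[pos - 1] > d:
                    best[pos] = best[pos - 1]
                    pos -= 1
                best[pos] = d
                worst = best[k - 1]
        eps = worst
        eps_out[i] = eps
        cac = 0
        cbc = 0
        cc = 0
        left = i - 1
        right = i + 1
        while left >= 0 or right < n:
            if left >= 0 and (right >= n or ci - c[left] <= c[right] - ci):
                j = left
                gap = ci - c[j]
                left -= 1
                from_left = True
            else:
                j = right
                gap = c[j] - ci
                right += 1
                from_left = False
            if gap >= eps:
                if from_left:
                    left = -1
                else:
                    right = n
                continue
            cc += 1
            if abs(ai - a[j]) < eps:
                cac += 1
            if abs(bi - b[j]) < eps:
                cbc += 1
        n_ac[i] = cac
        n_bc[i] = cbc
        n_c[i] = cc
    return eps_out, n_ac, n_bc, n_c


@njit(fastmath=False)
def _sweep_kernel_1d_multi(a, B, c, k):  # pragma: no cover - exercised via wrapper
    """Scalar specialization batched over the columns of B.

    Computes the neighbor statistics of I(a ; B[:, m] | c) for every
    column m in one outward sweep: the conditioning coordinate, the
    response coordinate and the sweep window are shared across columns.
    """
    n = a.shape[0]
    n_u = B.shape[1]
    eps_out = np.empty((n, n_u))
    n_ac = np.zeros((n, n_u), dtype=np.int64)
    n_bc = np.zeros((n, n_u), dtype=np.int64)
    n_c = np.zeros((n, n_u), dtype=np.int64)
    best = np.empty((n_u, k))
    worst = np.empty(n_u)
    for i in range(n):
        ai = a[i]
        ci = c[i]
        for m in range(n_u):
            for q in range(k):
                best[m, q] = np.inf
            worst[m] = np.inf
        wmax = np.inf
        left = i - 1
        right = i + 1
        while left >= 0 or right < n:
            if left >= 0 and (right >= n or ci - c[left] <= c[right] - ci):
                j = left
                gap = ci - c[j]
                left -= 1
                from_left = True
            else:
                j = right
                gap = c[j] - ci
                right += 1
                from_left = False
            if gap >= wmax:
                if from_left:
                    left = -1
                else:
                    right = n
                continue
            s = gap
            v = abs(ai - a[j])
            if v > s:
                s = v
            if s >= wmax:
                continue
            changed = False
            for m in range(n_u):
                if s >= worst[m]:
                    continue
                d = s
                v = abs(B[i, m] - B[j, m])
                if v > d:
                    d = v
                if d < worst[m]:
                    pos = k - 1
                    while pos > 0 and best[m, pos - 1] > d:
                        best[m, pos] = best[m, pos - 1]
                        pos -= 1
                    best[m, pos] = d
                    worst[m] = best[m, k - 1]
                    changed = True
            if changed:
                wmax = worst[0]
                for m in range(1, n_u):
                    if worst[m] > wmax:
                        wmax = worst[m]
        emax = worst[0]
        for m in range(n_u):
            eps_out[i, m] = worst[m]
            if worst[m] > emax:
                emax = worst[m]
        left = i - 1
        right = i + 1
        while left >= 0 or right < n:
            if left >= 0 and (right >= n or ci - c[left] <= c[right] - ci):
                j = left
                gap = ci - c[j]
                left -= 1
                from_left = True
            else:
                j = right
                gap = c[j] - ci
                right += 1
                from_left = False
            if gap >= emax:
                if from_left:
                    left = -1
                else:
                    right = n
                continue
            da = abs(ai - a[j])
            sac = gap if gap > da else da
            for m in range(n_u):
                eps = eps_out[i, m]
                if gap < eps:
                    n_c[i, m] += 1
                    if sac < eps:
                        n_ac[i, m] += 1
                    db = abs(B[i, m] - B[j, m])
                    if (gap if gap > db else db) < eps:
                        n_bc[i, m] += 1
        # column order of counts follows B's columns
    return eps_out, n_ac, n_bc, n_c


def cmi_counts_sweep_multi(a: np.ndarray, B: np.ndarray, c: np.ndarray,
                           k: int, order: np.ndarray):
    """Batched scalar neighbor statistics for several candidate sources."""
    a_s = np.ascontiguousarray(a[order, 0])
    B_s = np.ascontiguousarray(B[order])
    c_s = np.ascontiguousarray(c[order, 0])
    return _sweep_kernel_1d_multi(a_s, B_s, c_s, k)


def cmi_counts_sweep(a: np.ndarray, b: np.ndarray, c: np.ndarray, k: int,
                     order: np.ndarray | None = None):
    """Neighbor statistics via the sorted outward sweep (numba kernel).

    ``order`` may pass a precomputed argsort of ``c[:, 0]`` (reused
    across delay scans and surrogates, where the conditioning variable
    does not change).
    """
    if order is None:
        order = np.argsort(c[:, 0], kind="stable")
    if a.shape[1] == 1 and b.shape[1] == 1 and c.shape[1] == 1:
        eps, n_ac, n_bc, n_c = _sweep_kernel_1d(
            np.ascontiguousarray(a[order, 0]),
            np.ascontiguousarray(b[order, 0]),
            np.ascontiguousarray(c[order, 0]), k)
    else:
        eps, n_ac, n_bc, n_c = _sweep_kernel(
            np.ascontiguousarray(a[order]),
            np.ascontiguousarray(b[order]),
            np.ascontiguousarray(c[order]), k)
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    return eps[inv], n_ac[inv], n_bc[inv], n_c[inv]
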