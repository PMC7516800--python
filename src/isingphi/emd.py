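"""Exact earth-mover (Wasserstein-1) distances for small state spaces.

The integrated-information engine compares probability repertoires with the
earth-mover distance under the Hamming ground metric, and compares whole
cause-effect structures with a generalized EMD whose ground distances are
themselves repertoire EMDs.  Both are transportation problems; because small
differences (1e-6) decide minimum-information partitions, they must be solved
exactly, not approximately.

The solver is a successive-shortest-path min-cost-flow on the bipartite
transport graph, with Dijkstra and node potentials.  It is exact for any
nonnegative cost matrix and is compiled with numba since the engine calls it
hundreds of thousands of times per temperature sweep.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .states import hamming_distance_matrix

__all__ = ["transport_cost", "hamming_emd", "hamming_emd_diff", "effect_emd"]

_INF = 1e300
_EPS = 1e-12


@njit(cache=True)
def _transport(a, b, C):  # pragma: no cover - exercised via wrappers
    """Minimum cost of moving supply ``a`` onto demand ``b`` with unit costs
    ``C``; assumes sum(a) == sum(b) up to float error.

    Returns ``-1.0`` if the augmentation budget is exhausted (numerically
    degenerate instance); the caller falls back to an LP solve.
    """
    n1 = a.shape[0]
    n2 = b.shape[0]
    nv = n1 + n2
    excess = a.copy()
    deficit = b.copy()
    flow = np.zeros((n1, n2))
    pot = np.zeros(nv)
    dist = np.empty(nv)
    parent = np.empty(nv, dtype=np.int64)
    visited = np.empty(nv, dtype=np.uint8)

    budget = 20 * nv + 200
    rounds = 0
    while True:
        rounds += 1
        if rounds > budget:
            return -1.0
        # any remaining supply?
        total_excess = 0.0
        for i in range(n1):
            total_excess += excess[i]
        if total_excess <= _EPS:
            break

        # multi-source Dijkstra over the residual graph
        for v in range(nv):
            dist[v] = _INF
            parent[v] = -1
            visited[v] = 0
        for i in range(n1):
            if excess[i] > _EPS:
                dist[i] = 0.0
        while True:
            u = -1
            best = _INF
            for v in range(nv):
                if not visited[v] and dist[v] < best:
                    best = dist[v]
                    u = v
            if u < 0:
                break
            visited[u] = 1
            if u < n1:  # supply node: forward arcs to every demand node
                for j in range(n2):
                    v = n1 + j
                    if visited[v]:
                        continue
                    rc = C[u, j] + pot[u] - pot[v]
                    if rc < 0.0:  # float dust on the reduced costs
                        rc = 0.0
                    nd = dist[u] + rc
                    if nd < dist[v] - 1e-15:
                        dist[v] = nd
                        parent[v] = u
            else:  # demand node: residual arcs back along positive flow
                j = u - n1
                for i in range(n1):
                    if visited[i]:
                        continue
                    if flow[i, j] > _EPS:
                        rc = -C[i, j] + pot[u] - pot[i]
                        if rc < 0.0:
                            rc = 0.0
                        nd = dist[u] + rc
                        if nd < dist[i] - 1e-15:
                            dist[i] = nd
                            parent[i] = u

        # nearest demand node with unmet demand
        t = -1
        best = _INF
        for j in range(n2):
            if deficit[j] > _EPS and dist[n1 + j] < best:
                best = dist[n1 + j]
                t = n1 + j
        if t < 0:
            break  # nothing reachable: only float dust remains

        # bottleneck along the augmenting path
        bottleneck = deficit[t - n1]
        v = t
        while True:
            u = parent[v]
            if u < 0:
                if excess[v] < bottleneck:
                    bottleneck = excess[v]
                break
            if u >= n1:  # arc u(demand) -> v(supply) is residual
                f = flow[v, u - n1]
                if f < bottleneck:
                    bottleneck = f
            v = u

        # apply the augmentation
        v = t
        while True:
            u = parent[v]
            if u < 0:
                excess[v] -= bottleneck
                break
            if u < n1:  # forward arc supply u -> demand v
                flow[u, v - n1] += bottleneck
            else:  # residual arc demand u -> supply v
                flow[v, u - n1] -= bottleneck
            v = u
        deficit[t - n1] -= bottleneck

        # potential update keeps reduced costs nonnegative
        dt = dist[t]
        for v in range(nv):
            if dist[v] < dt:
                pot[v] += dist[v]
            else:
                pot[v] += dt

    cost = 0.0
    for i in range(n1):
        for j in range(n2):
            cost += flow[i, j] * C[i, j]
    return cost


def _transport_linprog(a, b, C):
    """Exact LP fallback for numerically degenerate transport instances."""
    from scipy.optimize import linprog

    n1, n2 = C.shape
    # variables x[i,j] >= 0; row sums a_i, column sums b_j (equalities, with
    # one redundant constraint dropped for numerical stability)
    A_eq = []
    b_eq = []
    for i in range(n1):
        row = np.zeros((n1, n2))
        row[i, :] = 1.0
        A_eq.append(row.ravel())
        b_eq.append(a[i])
    for j in range(n2 - 1):
        col = np.zeros((n1, n2))
        col[:, j] = 1.0
        A_eq.append(col.ravel())
        b_eq.append(b[j])
    res = linprog(
        C.ravel(), A_eq=np.array(A_eq), b_eq=np.array(b_eq),
        bounds=(0, None), method="highs",
    )
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def transport_cost(a: np.ndarray, b: np.ndarray, cost: np.ndarray) -> float:
    """Exact optimal-transport cost between two equal-mass weight vectors."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    cost = np.ascontiguousarray(cost, dtype=np.float64)
    if cost.shape != (a.size, b.size):
        raise ValueError("cost matrix shape does not match the distributions")
    if abs(a.sum() - b.sum()) > 1e-6:
        raise ValueError("distributions must have (nearly) equal total mass")
    if np.any(cost < 0):
        raise ValueError("costs must be nonnegative")
    value = float(_transport(a, b, cost))
    if value < 0:
        value = _transport_linprog(a, b, cost)
    return value


_hamming_cache: dict[int, np.ndarray] = {}


def _hamming(n: int) -> np.ndarray:
    if n not in _hamming_cache:
        _hamming_cache[n] = hamming_distance_matrix(n)
    return _hamming_cache[n]


@njit(cache=True)
def _emd_from_diff(diff, C):  # pragma: no cover - exercised via hamming_emd
    """Transport the signed difference ``diff`` over ground metric ``C``."""
    ns = 0
    nt = 0
    for x in diff:
        if x > _EPS:
            ns += 1
        elif x < -_EPS:
            nt += 1
    if ns == 0 or nt == 0:
        return 0.0
    a = np.empty(ns)
    b = np.empty(nt)
    si = np.empty(ns, dtype=np.int64)
    ti = np.empty(nt, dtype=np.int64)
    i = 0
    j = 0
    for k in range(diff.shape[0]):
        if diff[k] > _EPS:
            a[i] = diff[k]
            si[i] = k
            i += 1
        elif diff[k] < -_EPS:
            b[j] = -diff[k]
            ti[j] = k
            j += 1
    sub = np.empty((ns, nt))
    for i in range(ns):
        for j in range(nt):
            sub[i, j] = C[si[i], ti[j]]
    return _transport(a, b, sub)


def hamming_emd_diff(diff: np.ndarray, n_nodes: int) -> float:
    """EMD of a signed difference vector over the ``n_nodes`` Hamming cube.

    ``diff`` is a little-endian flat vector ``p - q``; used by the MIP search
    where repertoires are already flattened.
    """
    value = float(_emd_from_diff(diff, _hamming(n_nodes)))
    if value < 0:  # augmentation budget exhausted; exact LP fallback
        sup = diff > _EPS
        dem = diff < -_EPS
        C = _hamming(n_nodes)[np.ix_(sup.nonzero()[0], dem.nonzero()[0])]
        value = _transport_linprog(diff[sup], -diff[dem], C)
    return value


def hamming_emd(d1: np.ndarray, d2: np.ndarray) -> float:
    """EMD between two distributions over binary states with Hamming ground
    metric.

    Inputs are multilinear repertoires (one axis per node, singleton axes for
    nodes outside the purview); flattening is little-endian.  Because the
    Hamming metric is a true metric, shared mass never moves: only the signed
    difference is transported, which keeps the flow problem small.
    """
    if d1.shape != d2.shape:
        raise ValueError(f"shape mismatch: {d1.shape} vs {d2.shape}")
    n = int(sum(1 for s in d1.shape if s == 2))
    diff = np.ravel(d1 - d2, order="F")
    value = float(_emd_from_diff(diff, _hamming(n)))
    if value < 0:  # augmentation budget exhausted; exact LP fallback
        sup = diff > _EPS
        dem = diff < -_EPS
        C = _hamming(n)[np.ix_(sup.nonzero()[0], dem.nonzero()[0])]
        value = _transport_linprog(diff[sup], -diff[dem], C)
    return value


def effect_emd(d1: np.ndarray, d2: np.ndarray) -> float:
    """EMD between two *factorized* (effect) repertoires.

    Node updates are independent, so the EMD is the sum over nodes of the
    absolute difference in each node's OFF-probability.
    """
    if d1.shape != d2.shape:
        raise ValueError(f"shape mismatch: {d1.shape} vs {d2.shape}")
    total = 0.0
    for axis in range(d1.ndim):
        if d1.shape[axis] == 2:
            idx = [slice(None)] * d1.ndim
            idx[axis] = 0
            total += abs(d1[tuple(idx)].sum() - d2[tuple(idx)].sum())
    return float(total)
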