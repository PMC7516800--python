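"""Transition probability matrices of the synchronous Metropolis dynamics.

Under the synchronous update every node attempts a Metropolis flip
independently, conditioned on the current global configuration.  The dynamics
is therefore a Markov chain whose kernel factorizes over nodes: it is fully
specified by a *state-by-node* TPM, a ``2^n x n`` table whose entry ``(s, i)``
is the probability that node ``i`` is up (+1) at the next step given that the
system is in the configuration with little-endian code ``s``.  The
*state-by-state* kernel is the product of these per-node Bernoulli laws.

The state-by-node form is the input to the integrated-information engine; the
state-by-state form defines the stationary distribution used to validate the
simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components

from .networks import ConnectivityMatrix
from .states import all_spin_states

__all__ = [
    "StateByNodeTPM",
    "build_state_by_node_tpm",
    "expand_to_state_by_state",
    "collapse_to_state_by_node",
    "stationary_distribution",
    "write_tpm",
    "read_tpm",
]

#: Dense 2^n-row matrices become unwieldy beyond this size (and the Phi
#: engine needs n <= 5 anyway).
_MAX_NODES = 12


class NoUniqueStationaryDistributionError(RuntimeError):
    """The synchronous chain is reducible or periodic (e.g. the
    deterministic complement map of a zero-coupling network)."""


@dataclass(frozen=True)
class StateByNodeTPM:
    """Per-node 'up' probabilities for each current global state.

    ``probabilities`` has shape ``(2**n, n)``; rows are ordered by
    little-endian state code (node 0 = least significant bit, -1 -> 0,
    +1 -> 1).
    """

    probabilities: np.ndarray
    temperature: float
    network_label: str = ""

    def __post_init__(self):
        P = np.asarray(self.probabilities, dtype=float)
        n = P.shape[1] if P.ndim == 2 else -1
        if P.ndim != 2 or P.shape[0] != 2**n:
            raise ValueError(
                f"probabilities must have shape (2**n, n), got {P.shape}"
            )
        if np.any(P < 0) or np.any(P > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        P = P.copy()
        P.flags.writeable = False
        object.__setattr__(self, "probabilities", P)

    @property
    def n_nodes(self) -> int:
        return self.probabilities.shape[1]

    @property
    def n_states(self) -> int:
        return self.probabilities.shape[0]


def build_state_by_node_tpm(
    net: ConnectivityMatrix, temperature: float
) -> StateByNodeTPM:
    """Markov kernel of the synchronous Metropolis dynamics.

    For each current state ``s`` and node ``i``, the flip probability ``p``
    follows the Metropolis rule for ``dE_i = 2 s_i sum_j J_ij s_j``; the entry
    is ``p`` when ``s_i = -1`` (flip means turning up) and ``1 - p`` when
    ``s_i = +1`` (staying up means the flip was rejected).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if net.n_nodes > _MAX_NODES:
        raise ValueError(f"TPM construction limited to {_MAX_NODES} nodes")
    J = net.weights
    S = all_spin_states(net.n_nodes).astype(float)  # (2^n, n)
    de = 2.0 * S * (S @ J)  # dE for flipping each node in each state
    p_flip = np.where(de <= 0.0, 1.0, np.exp(-np.maximum(de, 0.0) / temperature))
    p_up = np.where(S < 0, p_flip, 1.0 - p_flip)
    return StateByNodeTPM(
        probabilities=p_up,
        temperature=temperature,
        network_label=net.label,
    )


def expand_to_state_by_state(sbn: StateByNodeTPM) -> np.ndarray:
    """Row-stochastic ``2^n x 2^n`` kernel: the product over nodes of each
    node's Bernoulli law (conditional independence of synchronous updates)."""
    n = sbn.n_nodes
    P = sbn.probabilities
    next_bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
    # T[s, s'] = prod_i P[s,i] if bit_i(s')=1 else (1 - P[s,i])
    T = np.ones((2**n, 2**n))
    for i in range(n):
        up = P[:, i][:, None]
        T *= np.where(next_bits[None, :, i] == 1, up, 1.0 - up)
    return T


def collapse_to_state_by_node(sbs: np.ndarray) -> np.ndarray:
    """Marginal per-node up probabilities of a state-by-state kernel.

    Inverse of :func:`expand_to_state_by_state` for conditionally
    independent kernels.
    """
    sbs = np.asarray(sbs)
    n_states = sbs.shape[0]
    n = int(np.log2(n_states))
    if 2**n != n_states or sbs.shape != (n_states, n_states):
        raise ValueError("kernel must be square with 2**n rows")
    next_bits = (np.arange(n_states)[:, None] >> np.arange(n)[None, :]) & 1
    return sbs @ next_bits.astype(float)


def stationary_distribution(sbs: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Unique left fixed point ``pi P = pi`` of the kernel.

    The Metropolis rule makes energy-lowering flips certain, so synchronous
    kernels contain structural zeros and are essentially never irreducible
    over the full state space.  Long-run visit frequencies still converge to
    a unique law whenever the support graph has exactly one *recurrent*
    class and that class is aperiodic; transient states carry zero
    stationary mass.  That weaker (and correct) condition is what is
    checked here; a :class:`NoUniqueStationaryDistributionError` is raised
    otherwise (the zero-coupling dynamics, a deterministic period-2
    complement map, is the canonical failure case).  Computed by dense
    eigen-decomposition with a power-iteration fallback.
    """
    P = np.asarray(sbs, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("kernel must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("kernel must be row-stochastic")

    support = (P > 0).astype(int)
    n_comp, labels = connected_components(support, connection="strong")
    # recurrent classes: strong components with no edges leaving them
    recurrent = []
    for c in range(n_comp):
        members = np.nonzero(labels == c)[0]
        outside = labels != c
        if not support[np.ix_(members, outside.nonzero()[0])].any():
            recurrent.append(members)
    if len(recurrent) != 1:
        raise NoUniqueStationaryDistributionError(
            f"chain has {len(recurrent)} recurrent classes; "
            "no unique stationary distribution"
        )
    members = recurrent[0]
    if _is_periodic(support[np.ix_(members, members)]):
        raise NoUniqueStationaryDistributionError(
            "recurrent class is periodic; no unique stationary distribution"
        )

    w, v = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    if np.abs(pi @ P - pi).sum() > tol:
        # eigen-solver struggled (near-degenerate spectrum); refine by power
        # iteration
        for _ in range(100_000):
            nxt = pi @ P
            if np.abs(nxt - pi).sum() < tol / 10:
                pi = nxt
                break
            pi = nxt
        if np.abs(pi @ P - pi).sum() > tol:
            raise NoUniqueStationaryDistributionError(
                "fixed-point iteration did not converge"
            )
    return pi


def _is_periodic(support: np.ndarray) -> bool:
    """Period > 1 test for an irreducible chain, via BFS level parities."""
    n = support.shape[0]
    if np.any(np.diag(support)):
        return False  # a self-loop makes an irreducible chain aperiodic
    from math import gcd

    depth = np.full(n, -1)
    depth[0] = 0
    stack = [0]
    g = 0
    while stack:
        u = stack.pop()
        for v in np.nonzero(support[u])[0]:
            if depth[v] < 0:
                depth[v] = depth[u] + 1
                stack.append(int(v))
            else:
                g = gcd(g, depth[u] + 1 - depth[v])
    return g != 1


def write_tpm(sbn: StateByNodeTPM, path: str | Path) -> None:
    """Persist a state-by-node TPM as CSV with a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, sbn.probabilities, fmt="%.17g", delimiter=",")
    meta = {
        "n_nodes": sbn.n_nodes,
        "ordering": "little-endian",
        "temperature": sbn.temperature,
        "network_label": sbn.network_label,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1)
    )


def read_tpm(path: str | Path) -> StateByNodeTPM:
    """Load a state-by-node TPM written by :func:`write_tpm`."""
    path = Path(path)
    P = np.loadtxt(path, delimiter=",", ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if meta.get("ordering", "little-endian") != "little-endian":
        raise ValueError(f"{path}: unsupported state ordering")
    return StateByNodeTPM(
        probabilities=P,
        temperature=float(meta.get("temperature", float("nan"))),
        network_label=meta.get("network_label", path.stem),
    )
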