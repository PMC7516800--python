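"""Random weighted connectivity matrices.

The structural input to the whole pipeline is a symmetric coupling matrix
``J`` with zero diagonal and nonnegative (ferromagnetic/excitatory) weights,
the kind of matrix produced by counting tractography fibers between brain
regions.  The study ensemble consists of fully connected n-node networks with
off-diagonal weights drawn independently from Uniform(0, 1) and then rescaled
so the single strongest coupling equals 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "generate_random_network",
    "normalize_weights",
    "generate_ensemble",
    "read_matrix",
    "write_matrix",
]


class DegenerateNetworkError(ValueError):
    """Raised when a matrix has no positive off-diagonal weight to normalize
    by."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """A symmetric, zero-diagonal coupling matrix with weights in [0, 1].

    Parameters
    ----------
    weights
        ``(n, n)`` array of couplings ``J_ij``.
    label
        Identifier used in output files.
    seed
        Seed the matrix was generated from; ``None`` for user-supplied
        matrices.
    """

    weights: np.ndarray
    label: str = "J"
    seed: int | None = None

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weights must be square, got shape {W.shape}")
        if W.shape[0] < 1:
            raise ValueError("network must have at least one node")
        if not np.allclose(W, W.T, atol=0.0):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("principal diagonal must be zero")
        if np.any(W < 0) or np.any(W > 1):
            raise ValueError("weights must lie in [0, 1]")
        W = W.copy()
        W.flags.writeable = False
        object.__setattr__(self, "weights", W)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def __eq__(self, other):
        if not isinstance(other, ConnectivityMatrix):
            return NotImplemented
        return (
            np.array_equal(self.weights, other.weights)
            and self.label == other.label
        )


def normalize_weights(
    weights: np.ndarray, label: str = "J", seed: int | None = None
) -> ConnectivityMatrix:
    """Rescale a symmetric nonnegative matrix so its strongest coupling is 1.

    The diagonal is forced to zero.  Raises :class:`DegenerateNetworkError`
    for an all-zero matrix, for which the rescaling is undefined.
    """
    W = np.array(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weights must be square, got shape {W.shape}")
    if not np.allclose(W, W.T, atol=0.0):
        raise ValueError("weights must be symmetric")
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    np.fill_diagonal(W, 0.0)
    wmax = W.max() if W.size else 0.0
    if wmax <= 0:
        raise DegenerateNetworkError(
            "all off-diagonal weights are zero; cannot normalize"
        )
    return ConnectivityMatrix(W / wmax, label=label, seed=seed)


def generate_random_network(
    n_nodes: int, seed: int, label: str | None = None
) -> ConnectivityMatrix:
    """Fully connected network with Uniform(0,1) weights, normalized to max 1.

    The ``n(n-1)/2`` upper-triangle weights are drawn independently and
    mirrored, so the coupling graph is undirected.
    """
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    rng = np.random.default_rng(seed)
    W = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    W[iu] = rng.uniform(0.0, 1.0, size=len(iu[0]))
    W = W + W.T
    return normalize_weights(
        W, label=label if label is not None else f"net-s{seed}", seed=seed
    )


def generate_ensemble(
    count: int, n_nodes: int, master_seed: int
) -> list[ConnectivityMatrix]:
    """Ensemble of ``count`` independent random networks.

    Member ``k`` uses a seed derived deterministically from
    ``(master_seed, k)`` via :class:`numpy.random.SeedSequence` spawning, so
    the ensemble is reproducible and members are statistically independent.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    children = np.random.SeedSequence(master_seed).spawn(count)
    nets = []
    for k, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2**31))
        nets.append(
            generate_random_network(
                n_nodes, seed, label=f"net-{master_seed}-{k:03d}"
            )
        )
    return nets


def write_matrix(net: ConnectivityMatrix, path: str | Path) -> None:
    """Write a connectivity matrix as whitespace-delimited text with a JSON
    sidecar (``<path>.json``) holding its provenance."""
    path = Path(path)
    np.savetxt(path, net.weights, fmt="%.17g")
    meta = {
        "label": net.label,
        "seed": net.seed,
        "n_nodes": net.n_nodes,
        "normalized": bool(np.isclose(net.weights.max(), 1.0)),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1)
    )


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    """Read a delimited-text connectivity matrix (and its sidecar, if
    present).

    Accepts whitespace- or comma-separated rows.  Rejects non-square,
    asymmetric or negative input with a message naming the offending cell.
    """
    path = Path(path)
    text = path.read_text()
    delim = "," if "," in text.splitlines()[0] else None
    W = np.loadtxt(path, delimiter=delim, ndmin=2)
    if W.shape[0] != W.shape[1]:
        raise ValueError(
            f"{path}: matrix is {W.shape[0]}x{W.shape[1]}, expected square"
        )
    neg = np.argwhere(W < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(f"{path}: negative weight at row {i}, column {j}")
    asym = np.argwhere(~np.isclose(W, W.T))
    if asym.size:
        i, j = asym[0]
        raise ValueError(
            f"{path}: asymmetric at row {i}, column {j} "
            f"({W[i, j]!r} != {W[j, i]!r})"
        )
    W = (W + W.T) / 2.0  # remove round-off asymmetry from text round-trips
    label, seed = path.stem, None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("label", label)
        seed = meta.get("seed")
    return ConnectivityMatrix(W, label=label, seed=seed)
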