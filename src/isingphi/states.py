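"""Binary spin-state coding shared across the package.

Spin configurations are length-``n`` vectors with entries in ``{-1, +1}``.
They are indexed by *little-endian* integer codes: node 0 is the least
significant bit, spin ``-1`` maps to bit 0 and spin ``+1`` to bit 1.  This is
the ordering convention of the IIT 3.0 reference toolbox, so state codes used
by the simulator, the transition-matrix builder and the integrated-information
engine are directly comparable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "spins_to_code",
    "code_to_spins",
    "all_spin_states",
    "hamming_distance_matrix",
]


def spins_to_code(spins: np.ndarray) -> int:
    """Little-endian integer code of a ±1 spin vector."""
    spins = np.asarray(spins)
    bits = (spins > 0).astype(np.int64)
    return int((bits << np.arange(bits.size)).sum())


def code_to_spins(code: int, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`spins_to_code`."""
    if not 0 <= code < 2**n_nodes:
        raise ValueError(f"state code {code} out of range for {n_nodes} nodes")
    bits = (code >> np.arange(n_nodes)) & 1
    return (2 * bits - 1).astype(np.int8)


def all_spin_states(n_nodes: int) -> np.ndarray:
    """All ``2**n`` spin configurations, row ``s`` being the state with code
    ``s``."""
    codes = np.arange(2**n_nodes)
    bits = (codes[:, None] >> np.arange(n_nodes)[None, :]) & 1
    return (2 * bits - 1).astype(np.int8)


def hamming_distance_matrix(n_nodes: int) -> np.ndarray:
    """Pairwise Hamming distances between all ``2**n`` state codes."""
    codes = np.arange(2**n_nodes)
    xor = codes[:, None] ^ codes[None, :]
    # popcount via uint8 view of the lookup-free bit trick
    dist = np.zeros_like(xor)
    while np.any(xor):
        dist += xor & 1
        xor >>= 1
    return dist.astype(np.float64)
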