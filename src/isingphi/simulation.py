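"""Metropolis dynamics for the generalized Ising model on a weighted graph.

The energy of a spin configuration ``s`` on a coupling matrix ``J`` is

    H(s) = - sum_{i<j} J_ij s_i s_j

with each unordered pair counted once and no external field (k_B = 1
throughout, so temperature is dimensionless).  A single-site Metropolis move
flips spin ``i`` with probability ``exp(-dE/T)`` when the flip raises the
energy by ``dE > 0`` and with probability 1 otherwise.

Two update schemes are provided:

``sequential``
    One uniformly chosen site is updated per iteration.  This chain satisfies
    detailed balance for the Boltzmann distribution and is the scheme used
    whenever equilibrium averages are compared against exact enumeration.

``synchronous``
    Every site attempts a flip simultaneously, each against the *current*
    configuration.  This is the Markov kernel encoded by the state-by-node
    transition probability matrix and is the default for the
    integrated-information pipeline.  It does not in general satisfy detailed
    balance, so the two schemes are not interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import ConnectivityMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTrace",
    "hamiltonian",
    "delta_energy",
    "flip_probability",
    "step_synchronous",
    "step_sequential",
    "simulate",
    "temperature_grid",
]

#: Iteration counts of the study protocol.
DEFAULT_THERMALIZATION = 500
DEFAULT_ITERATIONS = 2000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Metropolis run.

    ``temperature`` is in units of the coupling scale (k_B = 1).  The default
    protocol discards 500 thermalization steps and records 2000 iterations.
    """

    temperature: float
    n_thermalization: int = DEFAULT_THERMALIZATION
    n_iterations: int = DEFAULT_ITERATIONS
    update_mode: str = "synchronous"
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_thermalization < 0:
            raise ValueError("n_thermalization must be >= 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.update_mode not in ("synchronous", "sequential"):
            raise ValueError(f"unknown update_mode {self.update_mode!r}")


@dataclass(frozen=True)
class SimulationTrace:
    """Recorded measurement segment of a run.

    ``state_codes[t]`` is the little-endian code of the configuration after
    iteration ``t`` of the measurement phase; ``magnetization`` and ``energy``
    are the corresponding |sum(s)|/N and H values.
    """

    state_codes: np.ndarray
    magnetization: np.ndarray
    energy: np.ndarray
    config: SimulationConfig
    network_label: str = ""

    def __len__(self):
        return len(self.state_codes)


def hamiltonian(spins: np.ndarray, net: ConnectivityMatrix | np.ndarray) -> float:
    """Configuration energy ``-sum_{i<j} J_ij s_i s_j``."""
    J = net.weights if isinstance(net, ConnectivityMatrix) else np.asarray(net)
    s = np.asarray(spins, dtype=float)
    if s.shape[0] != J.shape[0]:
        raise ValueError(
            f"state has {s.shape[0]} spins but network has {J.shape[0]} nodes"
        )
    return float(-0.5 * s @ J @ s)


def delta_energy(
    spins: np.ndarray, net: ConnectivityMatrix | np.ndarray, i: int
) -> float:
    """Energy change from flipping spin ``i``: ``2 s_i sum_j J_ij s_j``.

    Exactly equals ``hamiltonian(flipped) - hamiltonian(spins)``.
    """
    J = net.weights if isinstance(net, ConnectivityMatrix) else np.asarray(net)
    s = np.asarray(spins, dtype=float)
    if not 0 <= i < s.shape[0]:
        raise IndexError(f"node index {i} out of range")
    return float(2.0 * s[i] * (J[i] @ s))


def flip_probability(delta_e: float, temperature: float) -> float:
    """Metropolis acceptance: 1 if the flip does not raise the energy, else
    ``exp(-dE/T)``."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return 1.0
    return float(np.exp(-delta_e / temperature))


def step_synchronous(
    spins: np.ndarray,
    net: ConnectivityMatrix | np.ndarray,
    temperature: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """All sites attempt a flip at once against the current state.

    One fresh uniform variate is drawn per node, in node order.
    """
    J = net.weights if isinstance(net, ConnectivityMatrix) else np.asarray(net)
    s = np.asarray(spins, dtype=np.int8)
    de = 2.0 * s * (J @ s)
    p = np.where(de <= 0, 1.0, np.exp(-np.maximum(de, 0.0) / temperature))
    flips = rng.random(s.shape[0]) < p
    out = s.copy()
    out[flips] = -out[flips]
    return out


def step_sequential(
    spins: np.ndarray,
    net: ConnectivityMatrix | np.ndarray,
    temperature: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One uniformly chosen site attempts a Metropolis flip.

    Draws (site, acceptance) in that order, so traces are reproducible for a
    given generator state.
    """
    J = net.weights if isinstance(net, ConnectivityMatrix) else np.asarray(net)
    s = np.asarray(spins, dtype=np.int8).copy()
    i = int(rng.integers(s.shape[0]))
    de = 2.0 * s[i] * (J[i] @ s)
    if de <= 0 or rng.random() < np.exp(-de / temperature):
        s[i] = -s[i]
    return s


def simulate(
    net: ConnectivityMatrix, config: SimulationConfig
) -> SimulationTrace:
    """Run the Metropolis protocol and record the measurement segment.

    The initial configuration is uniform random ±1.  ``n_thermalization``
    steps are discarded, then ``n_iterations`` steps are recorded with the
    state code, magnetization and energy logged after each.
    """
    J = net.weights
    n = net.n_nodes
    T = config.temperature
    rng = np.random.default_rng(config.seed)

    s = (2 * rng.integers(0, 2, size=n) - 1).astype(np.int8)
    total = config.n_thermalization + config.n_iterations

    codes = np.empty(config.n_iterations, dtype=np.int64)
    mags = np.empty(config.n_iterations)
    energies = np.empty(config.n_iterations)
    pows = 1 << np.arange(n)

    if config.update_mode == "synchronous":
        u = rng.random((total, n))
        for t in range(total):
            de = 2.0 * s * (J @ s)
            p = np.where(de <= 0.0, 1.0, np.exp(-np.maximum(de, 0.0) / T))
            s = np.where(u[t] < p, -s, s)
            k = t - config.n_thermalization
            if k >= 0:
                codes[k] = ((s > 0) * pows).sum()
                mags[k] = abs(int(s.sum())) / n
                energies[k] = -0.5 * float(s @ J @ s)
    else:
        sites = rng.integers(0, n, size=total)
        u = rng.random(total)
        sf = s.astype(float)
        E = -0.5 * float(sf @ J @ sf)
        for t in range(total):
            i = sites[t]
            de = 2.0 * s[i] * float(J[i] @ s)
            if de <= 0.0 or u[t] < np.exp(-de / T):
                s[i] = -s[i]
                E += de
            k = t - config.n_thermalization
            if k >= 0:
                codes[k] = ((s > 0) * pows).sum()
                mags[k] = abs(int(s.sum())) / n
                energies[k] = E
    return SimulationTrace(
        state_codes=codes,
        magnetization=mags,
        energy=energies,
        config=config,
        network_label=net.label,
    )


def temperature_grid(
    n_points: int = 200, low: float = 0.1, high: float = 4.0
) -> np.ndarray:
    """Log-uniformly spaced temperatures, endpoints inclusive.

    The study protocol samples 200 points in [0.1, 4].
    """
    if low <= 0 or low >= high:
        raise ValueError("need 0 < low < high")
    if n_points < 2:
        raise ValueError("need at least 2 grid points")
    return np.logspace(np.log10(low), np.log10(high), n_points)
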