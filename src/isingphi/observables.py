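"""Summary statistics of simulated observables.

An observable series is the per-iteration record of some quantity O over the
measurement phase.  The statistics follow the fluctuation conventions of the
study:

* magnetization              M = |sum_i s_i| / N
* time average               <O> = (1/Nt) sum_t O_t
* magnetic susceptibility    chi = (<M^2> - <M>^2) / T
* generalized susceptibility chi_O = <O^2> - <O>^2   (temporal variance,
  no division by temperature; applied to Phi this is chi_Phi)
* specific heat              Cv = (<E^2> - <E>^2) / T^2
* across-network variance    sigma_J^2(O) = <<O>^2>_J - <<O>>_J^2

All variances are population variances (1/N), matching the definitions
above.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "magnetization",
    "time_average",
    "magnetic_susceptibility",
    "generalized_susceptibility",
    "specific_heat",
    "ensemble_variance",
]


def magnetization(spins: np.ndarray) -> float:
    """Absolute net magnetization per spin, in [0, 1]."""
    s = np.asarray(spins)
    return float(abs(int(s.sum())) / s.size)


def time_average(series: np.ndarray) -> float:
    """Arithmetic mean over iterations."""
    return float(np.mean(series))


def _population_variance(series: np.ndarray) -> float:
    x = np.asarray(series, dtype=float)
    return float(np.mean(x * x) - np.mean(x) ** 2)


def magnetic_susceptibility(m_series: np.ndarray, temperature: float) -> float:
    """chi = (<M^2> - <M>^2) / T."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return max(_population_variance(m_series), 0.0) / temperature


def generalized_susceptibility(series: np.ndarray) -> float:
    """Temporal variance of an arbitrary observable (chi_O)."""
    return max(_population_variance(series), 0.0)


def specific_heat(e_series: np.ndarray, temperature: float) -> float:
    """Cv = (<E^2> - <E>^2) / T^2, the canonical fluctuation form."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return max(_population_variance(e_series), 0.0) / temperature**2


def ensemble_variance(per_network_means: np.ndarray) -> float:
    """Population variance of per-network time means across the ensemble."""
    return max(_population_variance(per_network_means), 0.0)
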