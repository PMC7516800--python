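import numpy as np
import pytest

from isingphi.networks import ConnectivityMatrix, generate_random_network


@pytest.fixture(scope="session")
def pair_net():
    """Two spins with unit coupling: every observable has a closed form."""
    return ConnectivityMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), label="pair")


@pytest.fixture(scope="session")
def zero_net3():
    """Zero-coupling 3-node network: three independent logical-NOT loops
    under the synchronous Metropolis kernel (every flip has dE = 0)."""
    return ConnectivityMatrix(np.zeros((3, 3)), label="zero3")


@pytest.fixture(scope="session")
def net3():
    return generate_random_network(3, seed=101)


@pytest.fixture(scope="session")
def net4():
    return generate_random_network(4, seed=202)


@pytest.fixture(scope="session")
def net5():
    return generate_random_network(5, seed=303)


def batch_standard_error(series: np.ndarray, n_batches: int = 20) -> float:
    """Standard error of a correlated Monte-Carlo series by batch means."""
    series = np.asarray(series, dtype=float)
    usable = (len(series) // n_batches) * n_batches
    means = series[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


@pytest.fixture(scope="session")
def mc_se():
    return batch_standard_error
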