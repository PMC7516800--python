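import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isingphi.exact import enumerate_canonical
from isingphi.networks import generate_random_network
from isingphi.simulation import (
    SimulationConfig,
    delta_energy,
    flip_probability,
    hamiltonian,
    simulate,
    step_sequential,
    step_synchronous,
    temperature_grid,
)
from isingphi.states import code_to_spins


class TestHamiltonian:
    def test_pair_aligned_and_antialigned(self, pair_net):
        assert hamiltonian(np.array([1, 1]), pair_net) == -1.0
        assert hamiltonian(np.array([1, -1]), pair_net) == 1.0

    def test_all_up_equals_minus_total_coupling(self, net5):
        total = net5.weights[np.triu_indices(5, k=1)].sum()
        assert hamiltonian(np.ones(5), net5) == pytest.approx(-total)

    def test_size_mismatch(self, net5):
        with pytest.raises(ValueError):
            hamiltonian(np.ones(4), net5)


class TestDeltaEnergy:
    def test_zero_coupling_always_zero(self, zero_net3):
        for code in range(8):
            s = code_to_spins(code, 3)
            assert all(delta_energy(s, zero_net3, i) == 0 for i in range(3))

    def test_pair_example(self, pair_net):
        assert delta_energy(np.array([1, 1]), pair_net, 0) == 2.0

    def test_matches_explicit_hamiltonian_difference(self):
        rng = np.random.default_rng(42)
        for seed in range(10):
            net = generate_random_network(5, seed=seed)
            s = (2 * rng.integers(0, 2, size=5) - 1).astype(np.int8)
            i = int(rng.integers(5))
            flipped = s.copy()
            flipped[i] = -flipped[i]
            expected = hamiltonian(flipped, net) - hamiltonian(s, net)
            assert delta_energy(s, net, i) == pytest.approx(
                expected, abs=1e-12
            )

    def test_index_out_of_range(self, pair_net):
        with pytest.raises(IndexError):
            delta_energy(np.array([1, 1]), pair_net, 2)


class TestFlipProbability:
    @pytest.mark.parametrize("de", [-0.5, 0.0])
    def test_energy_lowering_or_neutral_always_accepted(self, de):
        assert flip_probability(de, 0.7) == 1.0

    def test_boltzmann_factor(self):
        assert flip_probability(1.0, 1.0) == pytest.approx(np.exp(-1))

    def test_requires_positive_temperature(self):
        with pytest.raises(ValueError):
            flip_probability(1.0, 0.0)


class TestSteps:
    def test_synchronous_zero_coupling_is_complement(self, zero_net3):
        rng = np.random.default_rng(0)
        s = np.array([1, -1, 1], dtype=np.int8)
        out = step_synchronous(s, zero_net3, 1.0, rng)
        assert np.array_equal(out, -s)

    def test_synchronous_ground_state_frozen_at_low_temperature(self, net5):
        rng = np.random.default_rng(0)
        s = np.ones(5, dtype=np.int8)
        out = step_synchronous(s, net5, 1e-9, rng)
        assert np.array_equal(out, s)

    def test_synchronous_flip_frequencies_match_metropolis_rule(self, net4):
        rng = np.random.default_rng(7)
        s = code_to_spins(5, 4)
        n_draws = 20_000
        flips = np.zeros(4)
        for _ in range(n_draws):
            out = step_synchronous(s, net4, 1.3, rng)
            flips += out != s
        for i in range(4):
            p = flip_probability(delta_energy(s, net4, i), 1.3)
            se = np.sqrt(max(p * (1 - p), 1e-12) / n_draws)
            assert abs(flips[i] / n_draws - p) < 3 * se + 1e-9

    def test_sequential_changes_at_most_one_spin(self, net5):
        rng = np.random.default_rng(3)
        s = code_to_spins(19, 5)
        for _ in range(50):
            out = step_sequential(s, net5, 0.8, rng)
            assert (out != s).sum() <= 1
            s = out

    def test_sequential_detailed_balance(self, net3):
        """pi(a) P(a->b) = pi(b) P(b->a) for the Boltzmann distribution,
        checked analytically on every single-spin-flip pair."""
        T = 1.1
        exact = enumerate_canonical(net3, T)
        pi = exact.state_probabilities
        for a in range(8):
            sa = code_to_spins(a, 3)
            for i in range(3):
                b = a ^ (1 << i)
                p_ab = flip_probability(delta_energy(sa, net3, i), T) / 3
                sb = code_to_spins(b, 3)
                p_ba = flip_probability(delta_energy(sb, net3, i), T) / 3
                assert pi[a] * p_ab == pytest.approx(pi[b] * p_ba, rel=1e-10)


class TestSimulate:
    def test_trace_lengths_and_determinism(self, net5):
        config = SimulationConfig(temperature=1.5, seed=5)
        t1 = simulate(net5, config)
        t2 = simulate(net5, config)
        assert len(t1) == 2000
        assert np.array_equal(t1.state_codes, t2.state_codes)
        short = simulate(
            net5, SimulationConfig(temperature=1.5, n_iterations=1, seed=5)
        )
        assert len(short) == 1

    def test_logged_energy_consistent_with_hamiltonian(self, net5):
        config = SimulationConfig(
            temperature=2.0, n_iterations=200, update_mode="sequential", seed=9
        )
        trace = simulate(net5, config)
        for k in (0, 57, 199):
            s = code_to_spins(int(trace.state_codes[k]), 5)
            assert trace.energy[k] == pytest.approx(
                hamiltonian(s, net5), abs=1e-9
            )

    def test_pair_energy_matches_closed_form(self, pair_net, mc_se):
        config = SimulationConfig(
            temperature=1.0,
            n_iterations=20_000,
            update_mode="sequential",
            seed=11,
        )
        trace = simulate(pair_net, config)
        se = mc_se(trace.energy)
        assert abs(trace.energy.mean() - (-np.tanh(1.0))) < 3 * se

    def test_infinite_temperature_magnetization(self, net5, mc_se):
        """At T = 100 the stationary law is uniform: <M> = E|sum of 5
        coin flips|/5 = 0.375."""
        config = SimulationConfig(
            temperature=100.0,
            n_iterations=30_000,
            update_mode="sequential",
            seed=13,
        )
        trace = simulate(net5, config)
        se = mc_se(trace.magnetization)
        assert abs(trace.magnetization.mean() - 0.375) < 3 * se


class TestTemperatureGrid:
    def test_default_protocol_grid(self):
        grid = temperature_grid()
        assert len(grid) == 200
        assert grid[0] == pytest.approx(0.1)
        assert grid[-1] == pytest.approx(4.0)

    def test_two_points(self):
        assert temperature_grid(2).tolist() == pytest.approx([0.1, 4.0])

    def test_log_spacing_constant_ratio(self):
        grid = temperature_grid(50)
        ratios = grid[1:] / grid[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    @pytest.mark.parametrize("low,high", [(0.0, 4.0), (-1.0, 4.0), (4.0, 0.1)])
    def test_invalid_bounds(self, low, high):
        with pytest.raises(ValueError):
            temperature_grid(10, low, high)


def test_simulation_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(temperature=-1.0)
    with pytest.raises(ValueError):
        SimulationConfig(temperature=1.0, update_mode="spiral")
    with pytest.raises(ValueError):
        SimulationConfig(temperature=1.0, n_iterations=0)


class TestHypothesisProperties:
    """Randomized invariants of the energy functions (seeded/derandomized)."""

    @given(
        st.integers(min_value=0, max_value=2**5 - 1),
        st.integers(min_value=0, max_value=4),
        st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_delta_energy_is_exact_hamiltonian_difference(
        self, code, site, seed
    ):
        net = generate_random_network(5, seed=seed)
        s = code_to_spins(code, 5)
        flipped = s.copy()
        flipped[site] = -flipped[site]
        assert delta_energy(s, net, site) == pytest.approx(
            hamiltonian(flipped, net) - hamiltonian(s, net), abs=1e-12
        )

    @given(st.integers(min_value=0, max_value=2**5 - 1))
    @settings(max_examples=32, derandomize=True, deadline=None)
    def test_hamiltonian_invariant_under_global_flip(self, code):
        net = generate_random_network(5, seed=1234)
        s = code_to_spins(code, 5)
        assert hamiltonian(s, net) == pytest.approx(hamiltonian(-s, net))
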