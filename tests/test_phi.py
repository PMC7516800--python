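import json
from pathlib import Path

import numpy as np
import pytest

from isingphi import phi as phi_mod
from isingphi.networks import ConnectivityMatrix, generate_random_network
from isingphi.phi import (
    CAUSE,
    EFFECT,
    PhiEngine,
    Repertoire,
    big_phi,
    cause_repertoire,
    compute_ces,
    effect_repertoire,
    phi_over_trace,
    repertoire_emd,
    small_phi,
)
from isingphi.simulation import SimulationConfig, simulate
from isingphi.tpm import StateByNodeTPM, build_state_by_node_tpm

REFERENCE = json.loads(
    (Path(__file__).parent / "data" / "phi_reference.json").read_text()
)


@pytest.fixture(autouse=True)
def _fresh_engines():
    yield
    phi_mod.clear_caches()


@pytest.fixture(scope="module")
def zero_tpm3(zero_net3):
    return build_state_by_node_tpm(zero_net3, 1.0)


def uniform_tpm(n):
    return StateByNodeTPM(
        probabilities=np.full((2**n, n), 0.5), temperature=1.0
    )


class TestRepertoires:
    def test_not_loop_cause_is_point_mass_on_inverse(self, zero_tpm3):
        # each node is a deterministic NOT of itself; seeing it up now means
        # it was down before
        rep = cause_repertoire(zero_tpm3, 0b001, mechanism=(0,), purview=(0,))
        assert rep.distribution == pytest.approx([1.0, 0.0])

    def test_not_loop_effect_is_point_mass_on_flip(self, zero_tpm3):
        rep = effect_repertoire(zero_tpm3, 0b001, mechanism=(0,), purview=(0,))
        assert rep.distribution == pytest.approx([1.0, 0.0])

    def test_unconnected_purview_is_uniform(self, zero_tpm3):
        # node 0 gets no input from node 1, so its state says nothing about
        # node 1's past
        rep = cause_repertoire(zero_tpm3, 0b001, mechanism=(0,), purview=(1,))
        assert rep.distribution == pytest.approx([0.5, 0.5])

    def test_repertoires_normalized_on_random_tpms(self, net4):
        tpm = build_state_by_node_tpm(net4, 1.3)
        for mech in [(0,), (1, 3), (0, 1, 2, 3)]:
            for purv in [(0,), (0, 2), (0, 1, 2, 3)]:
                c = cause_repertoire(tpm, 9, mech, purv)
                e = effect_repertoire(tpm, 9, mech, purv)
                assert c.distribution.sum() == pytest.approx(1.0)
                assert e.distribution.sum() == pytest.approx(1.0)

    def test_match_reference_toolbox_within_1e10(self):
        checked = 0
        for case in REFERENCE:
            if "repertoires" not in case:
                continue
            net = generate_random_network(case["n"], seed=case["seed"])
            tpm = build_state_by_node_tpm(net, case["temperature"])
            for rec in case["repertoires"]:
                mech = tuple(rec["mechanism"])
                purv = tuple(rec["purview"])
                c = cause_repertoire(tpm, case["state"], mech, purv)
                e = effect_repertoire(tpm, case["state"], mech, purv)
                assert np.allclose(
                    c.distribution, rec["cause"], atol=1e-10
                )
                assert np.allclose(
                    e.distribution, rec["effect"], atol=1e-10
                )
                checked += 1
        assert checked >= 30


class TestRepertoireEmd:
    def test_identity_and_point_masses(self):
        p = Repertoire((0,), np.array([1.0, 0.0]))
        q = Repertoire((0,), np.array([0.0, 1.0]))
        assert repertoire_emd(p, p) == 0.0
        assert repertoire_emd(p, q) == pytest.approx(1.0)
        pp = Repertoire((0, 1), np.array([1.0, 0, 0, 0]))
        qq = Repertoire((0, 1), np.array([0, 0, 0, 1.0]))
        assert repertoire_emd(pp, qq) == pytest.approx(2.0)

    def test_mismatched_purviews_rejected(self):
        p = Repertoire((0,), np.array([0.5, 0.5]))
        q = Repertoire((1,), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            repertoire_emd(p, q)


class TestSmallPhi:
    def test_multi_node_mechanism_in_product_system_reducible(self, zero_tpm3):
        for direction in (CAUSE, EFFECT):
            res = small_phi(zero_tpm3, 0, (0, 1), direction)
            assert res.phi == 0.0

    def test_not_mechanism_phi_is_half(self, zero_tpm3):
        # severing the NOT mechanism from its purview leaves the uniform
        # repertoire; EMD(point mass, uniform over one bit) = 0.5, the
        # reference-toolbox value
        for direction in (CAUSE, EFFECT):
            res = small_phi(zero_tpm3, 0, (1,), direction)
            assert res.phi == pytest.approx(0.5)
            assert res.purview == (1,)


class TestCes:
    def test_zero_coupling_only_single_node_concepts(self, zero_tpm3):
        ces = compute_ces(zero_tpm3, 0b101)
        assert sorted(c.mechanism for c in ces.concepts) == [(0,), (1,), (2,)]
        for c in ces.concepts:
            assert c.phi == pytest.approx(0.5)

    def test_uniform_tpm_has_no_concepts(self):
        ces = compute_ces(uniform_tpm(3), 0)
        assert len(ces) == 0

    def test_concept_count_bound(self, net3):
        tpm = build_state_by_node_tpm(net3, 1.0)
        ces = compute_ces(tpm, 3)
        assert len(ces) <= 2**3 - 1


class TestBigPhi:
    def test_zero_coupling_reducible_everywhere(self, zero_net3):
        for T in (0.5, 1.0, 4.0):
            tpm = build_state_by_node_tpm(zero_net3, T)
            for state in range(8):
                assert big_phi(tpm, state).phi == 0.0

    def test_single_node_system_is_zero(self):
        tpm = StateByNodeTPM(
            probabilities=np.array([[0.9], [0.2]]), temperature=1.0
        )
        assert big_phi(tpm, 0).phi == 0.0
        assert big_phi(tpm, 1).phi == 0.0

    def test_uniform_tpm_is_zero(self):
        assert big_phi(uniform_tpm(3), 5).phi == 0.0

    def test_matches_reference_toolbox_3node_sample(self):
        for case in REFERENCE[:12]:
            net = generate_random_network(case["n"], seed=case["seed"])
            tpm = build_state_by_node_tpm(net, case["temperature"])
            res = big_phi(tpm, case["state"])
            assert res.phi == pytest.approx(case["phi"], abs=1e-6)
            phi_mod.clear_caches()

    def test_invariant_under_global_spin_flip(self, net3):
        """The field-free dynamics commute with complementation, so Phi of a
        state equals Phi of its complement (checked through two independent
        computations, bypassing the symmetry-aware cache)."""
        tpm = build_state_by_node_tpm(net3, 1.1)
        eng = PhiEngine(tpm)
        for state in (0, 3, 5):
            a = eng._compute_big_phi(state)
            b = eng._compute_big_phi(state ^ 0b111)
            assert a.phi == pytest.approx(b.phi, abs=1e-6)

    def test_invariant_under_node_relabeling(self, net3):
        perm = [2, 0, 1]
        W = net3.weights[np.ix_(perm, perm)]
        permuted = ConnectivityMatrix(W, label="permuted")
        t1 = build_state_by_node_tpm(net3, 1.4)
        t2 = build_state_by_node_tpm(permuted, 1.4)
        # state 0b011 maps: new node k holds old node perm[k]
        state = 0b011
        mapped = sum(((state >> perm[k]) & 1) << k for k in range(3))
        assert big_phi(t1, state).phi == pytest.approx(
            big_phi(t2, mapped).phi, abs=1e-6
        )

    def test_size_guard(self):
        with pytest.raises(ValueError, match="5 nodes"):
            PhiEngine(
                StateByNodeTPM(
                    probabilities=np.full((64, 6), 0.5), temperature=1.0
                )
            )

    def test_cached_result_flagged(self, net3):
        tpm = build_state_by_node_tpm(net3, 0.9)
        first = big_phi(tpm, 2)
        again = big_phi(tpm, 2)
        assert not first.from_cache and again.from_cache
        assert first.phi == again.phi


class TestPhiOverTrace:
    def test_single_state_trace_has_zero_susceptibility(self, net3):
        tpm = build_state_by_node_tpm(net3, 0.2)
        trace = simulate(
            net3,
            SimulationConfig(
                temperature=0.2, n_iterations=50, n_thermalization=500,
                update_mode="sequential", seed=1,
            ),
        )
        if len(np.unique(trace.state_codes)) == 1:
            res = phi_over_trace(trace, tpm)
            assert res.chi_phi == 0.0

    def test_cache_accounting(self, net3):
        tpm = build_state_by_node_tpm(net3, 2.0)
        trace = simulate(
            net3,
            SimulationConfig(
                temperature=2.0, n_iterations=500,
                update_mode="sequential", seed=2,
            ),
        )
        res = phi_over_trace(trace, tpm)
        assert res.n_evaluations + res.n_cache_hits == len(trace)
        assert set(res.phi_by_state) == set(np.unique(trace.state_codes))

    def test_boltzmann_weighting_consistent_with_long_visits(self, net3):
        """Visit-frequency weighting over a long sequential trace converges
        to weighting every state's Phi by its exact Boltzmann
        probability."""
        from isingphi.exact import enumerate_canonical

        T = 2.5
        tpm = build_state_by_node_tpm(net3, T)
        trace = simulate(
            net3,
            SimulationConfig(
                temperature=T, n_iterations=60_000,
                update_mode="sequential", seed=3,
            ),
        )
        visit = phi_over_trace(trace, tpm, weighting="visit")
        boltzmann = enumerate_canonical(net3, T).state_probabilities
        weighted = phi_over_trace(
            trace, tpm, weighting="stationary", state_weights=boltzmann
        )
        assert visit.phi_mean == pytest.approx(weighted.phi_mean, abs=0.02)

    def test_stationary_weighting_raises_for_periodic_kernel(self, net3):
        from isingphi.tpm import NoUniqueStationaryDistributionError

        T = 2.5
        tpm = build_state_by_node_tpm(net3, T)
        trace = simulate(
            net3,
            SimulationConfig(temperature=T, n_iterations=100, seed=4),
        )
        with pytest.raises(NoUniqueStationaryDistributionError):
            phi_over_trace(trace, tpm, weighting="stationary")
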