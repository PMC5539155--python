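import numpy as np
import pytest

from graphemd import (
    GeneNetwork,
    incidence_matrix,
    shortest_path_costs,
    w1_coupling,
    w1_dual,
    w1_flux,
)

from .conftest import delta, random_connected_network, random_prob


class TestGroundMetric:
    def test_triangle_all_costs_one(self):
        net = GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        c = shortest_path_costs(net).c
        off = c[~np.eye(3, dtype=bool)]
        assert (off == 1).all()
        assert (np.diag(c) == 0).all()

    def test_path_hop_counts(self, path_network):
        c = shortest_path_costs(path_network).c
        assert c[0, 2] == 2 and c[0, 1] == 1
        np.testing.assert_array_equal(c, c.T)

    def test_disconnected_network_rejected(self):
        net = GeneNetwork.from_edges([("A", "B"), ("C", "D")])
        with pytest.raises(ValueError, match="disconnected"):
            shortest_path_costs(net)


class TestIncidenceMatrix:
    def test_structure(self, path_network):
        d = incidence_matrix(path_network).toarray()
        assert d.shape == (3, 2)
        # one +1 (head = smaller node index) and one -1 per column
        assert (d.sum(axis=0) == 0).all()
        assert ((d == 1).sum(axis=0) == 1).all() and ((d == -1).sum(axis=0) == 1).all()
        # edge (A,B): head A; edge (B,C): head B
        assert d[0, 0] == 1 and d[1, 0] == -1
        assert d[1, 1] == 1 and d[2, 1] == -1


class TestFluxFormulation:
    def test_identical_measures_zero_distance(self, path_network):
        rho = np.array([0.2, 0.5, 0.3])
        dist, _ = w1_flux(path_network, rho, rho)
        assert dist == pytest.approx(0.0, abs=1e-9)

    def test_delta_to_delta_is_hop_count(self, path_network):
        dist, flow = w1_flux(path_network, delta(3, 0), delta(3, 2))
        assert dist == pytest.approx(2.0, abs=1e-7)
        assert flow.u.shape == (2,)  # one flux variable per edge

    def test_half_mass_one_hop(self, path_network):
        dist, _ = w1_flux(path_network, np.array([0.5, 0.5, 0.0]), np.array([0.0, 0.5, 0.5]))
        assert dist == pytest.approx(1.0, abs=1e-7)

    def test_divergence_constraint_satisfied(self):
        rng = np.random.default_rng(5)
        net = random_connected_network(rng, 15)
        r0, r1 = random_prob(rng, 15), random_prob(rng, 15)
        _, flow = w1_flux(net, r0, r1)
        d = incidence_matrix(net)
        assert np.abs(r0 - r1 - d @ flow.u).max() <= 1e-7

    def test_unequal_masses_rejected(self, path_network):
        with pytest.raises(ValueError, match="unequal"):
            w1_flux(path_network, np.array([0.5, 0.3, 0.1]), np.array([0.4, 0.3, 0.3]))


class TestCouplingFormulation:
    def test_identity_coupling(self, path_network):
        metric = shortest_path_costs(path_network)
        rho = np.array([0.1, 0.6, 0.3])
        dist, plan = w1_coupling(metric, rho, rho)
        assert dist == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(np.diag(plan.mu), rho, atol=1e-8)

    def test_single_edge_unit_move(self):
        net = GeneNetwork.from_edges([("A", "B")])
        dist, plan = w1_coupling(shortest_path_costs(net), delta(2, 0), delta(2, 1))
        assert dist == pytest.approx(1.0, abs=1e-9)
        assert plan.mu.shape == (2, 2)  # n^2 variables, vs m for the flux LP

    def test_marginals_match(self, path_network):
        rng = np.random.default_rng(8)
        r0, r1 = random_prob(rng, 3), random_prob(rng, 3)
        _, plan = w1_coupling(shortest_path_costs(path_network), r0, r1)
        np.testing.assert_allclose(plan.mu.sum(axis=1), r0, atol=1e-8)
        np.testing.assert_allclose(plan.mu.sum(axis=0), r1, atol=1e-8)

    def test_size_guard_refuses_large_instances(self):
        from graphemd.transport import GroundMetric

        metric = GroundMetric(c=np.zeros((300, 300)))
        with pytest.raises(ValueError, match="w1_flux"):
            w1_coupling(metric, np.ones(300) / 300, np.ones(300) / 300)


class TestDualFormulation:
    def test_single_edge(self):
        net = GeneNetwork.from_edges([("A", "B")])
        dist, pot = w1_dual(net, delta(2, 0), delta(2, 1))
        assert dist == pytest.approx(1.0, abs=1e-7)
        # optimal potential drops by exactly 1 across the edge
        assert abs(pot.f[0] - pot.f[1]) == pytest.approx(1.0, abs=1e-7)

    def test_path_delta_pair(self, path_network):
        dist, pot = w1_dual(path_network, delta(3, 0), delta(3, 2))
        assert dist == pytest.approx(2.0, abs=1e-7)
        # both edge constraints are tight: f differs by 1 on each edge
        assert abs(pot.f[0] - pot.f[1]) == pytest.approx(1.0, abs=1e-7)
        assert abs(pot.f[1] - pot.f[2]) == pytest.approx(1.0, abs=1e-7)

    def test_potential_is_edgewise_lipschitz(self):
        rng = np.random.default_rng(21)
        net = random_connected_network(rng, 12)
        _, pot = w1_dual(net, random_prob(rng, 12), random_prob(rng, 12))
        for i, j in net.edge_index_pairs():
            assert abs(pot.f[i] - pot.f[j]) <= 1 + 1e-7


class TestCrossFormulationAgreement:
    """Strong duality: all three LPs compute the same number."""

    @pytest.mark.parametrize("seed", range(10))
    def test_three_way_agreement(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        net = random_connected_network(rng, n)
        r0, r1 = random_prob(rng, n), random_prob(rng, n)
        d_flux, _ = w1_flux(net, r0, r1)
        d_coup, _ = w1_coupling(shortest_path_costs(net), r0, r1)
        d_dual, _ = w1_dual(net, r0, r1)
        assert d_flux == pytest.approx(d_coup, abs=1e-6)
        assert d_flux == pytest.approx(d_dual, abs=1e-6)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(99)
        net = random_connected_network(rng, 10)
        for _ in range(10):
            a, b, c = (random_prob(rng, 10) for _ in range(3))
            dab, _ = w1_flux(net, a, b)
            dba, _ = w1_flux(net, b, a)
            dbc, _ = w1_flux(net, b, c)
            dac, _ = w1_flux(net, a, c)
            daa, _ = w1_flux(net, a, a)
            assert dab >= 0 and daa <= 1e-9
            assert dab == pytest.approx(dba, abs=1e-8)
            assert dac <= dab + dbc + 1e-8
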