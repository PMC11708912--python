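"""Network simulators: structure, precision matrices, Gaussian sampling."""

import numpy as np
import pytest

from mdsd.networks import (make_hub_network, make_inter_hub_network,
                           make_network, make_scale_free_network,
                           make_star_network,
                           make_two_component_hub_network,
                           precision_from_adjacency, sample_gaussian)

ALL_MAKERS = [
    lambda seed: make_star_network(40, 4, seed=seed),
    lambda seed: make_hub_network(40, 2, seed=seed),
    lambda seed: make_two_component_hub_network(40, 1, seed=seed),
    lambda seed: make_scale_free_network(40, seed=seed),
    lambda seed: make_inter_hub_network(41, 2, seed=seed),
]


class TestStar:
    def test_single_star_p4(self):
        net = make_star_network(4, 1)
        edges = set(map(tuple, net.to_dict()["edges"]))
        assert edges == {(1, 2), (1, 3), (1, 4)}
        assert net.hub_ids == {1}

    def test_fig1_configuration(self):
        net = make_star_network(500, 5)
        deg = net.degrees
        hubs = sorted(h - 1 for h in net.hub_ids)
        assert len(hubs) == 5
        assert all(deg[h] == 99 for h in hubs)
        non_hubs = np.setdiff1d(np.arange(500), hubs)
        assert np.all(deg[non_hubs] == 1)
        assert net.n_edges == 495

    def test_three_two_node_stars(self):
        net = make_star_network(6, 3)
        # brute-force degree count: every node pairs with its center only
        assert sorted(net.degrees.tolist()) == [1] * 6
        assert net.n_edges == 3

    def test_remainder_goes_to_last_component(self):
        net = make_star_network(7, 2)
        assert sorted(net.degrees.tolist()) == [1, 1, 1, 1, 1, 2, 3]

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_star_network(5, 3)


class TestHub:
    def test_hub_degrees_dominate(self):
        net = make_hub_network(100, 2, seed=5)
        deg = net.degrees
        hubs = [h - 1 for h in net.hub_ids]
        non_hubs = np.setdiff1d(np.arange(100), hubs)
        assert deg[hubs].min() > deg[non_hubs].max()
        # expected hub degree about 0.7 * (p - 1)
        assert abs(deg[hubs].mean() - 0.7 * 99) < 15

    def test_zero_background_only_hub_spokes(self):
        net = make_hub_network(50, 1, background_density=0.0, seed=0)
        hub = next(iter(net.hub_ids)) - 1
        off_hub = np.delete(np.arange(50), hub)
        sub = net.adjacency[np.ix_(off_hub, off_hub)]
        assert sub.sum() == 0

    def test_invalid_hub_count(self):
        with pytest.raises(ValueError):
            make_hub_network(10, 0)


class TestTwoComponent:
    def test_block_diagonal_no_crossing(self):
        net = make_two_component_hub_network(200, 1, seed=1)
        half = 100
        assert net.adjacency[:half, half:].sum() == 0
        assert len(net.hub_ids) == 2

    def test_odd_p_split(self):
        net = make_two_component_hub_network(31, 1, seed=2)
        assert net.adjacency[:16, 16:].sum() == 0


class TestScaleFree:
    def test_tree_structure_m1(self):
        net = make_scale_free_network(100, 1, seed=3)
        assert net.n_edges == 99
        import networkx as nx
        g = nx.from_numpy_array(net.adjacency)
        assert nx.is_connected(g)

    def test_p2_single_edge_no_hubs(self):
        net = make_scale_free_network(2, 1, seed=0)
        assert net.n_edges == 1
        assert net.hub_ids == frozenset()

    def test_degree_distribution_right_skewed(self):
        from mdsd.screening import degree_skewness
        n_skewed = sum(
            degree_skewness(make_scale_free_network(500, seed=s).degrees) > 0.5
            for s in range(20))
        assert n_skewed >= 18  # power-law-like in essentially every draw


class TestInterHub:
    def test_bottleneck_structure(self):
        net = make_inter_hub_network(21, 2, seed=0)
        deg = net.degrees
        bottleneck = 20  # last node by construction
        assert bottleneck + 1 in net.hub_ids
        assert deg[bottleneck] == 2
        module_hubs = [h - 1 for h in net.hub_ids if h - 1 != bottleneck]
        assert min(deg[h] for h in module_hubs) >= 9
        assert deg[bottleneck] < max(deg[h] for h in module_hubs)

    def test_bottleneck_is_cut_vertex(self):
        import networkx as nx
        net = make_inter_hub_network(41, 2, seed=1)
        g = nx.from_numpy_array(net.adjacency)
        assert nx.is_connected(g)
        g.remove_node(40)
        assert not nx.is_connected(g)


class TestPrecision:
    def test_empty_adjacency_diagonal(self):
        theta = precision_from_adjacency(np.zeros((4, 4)))
        assert np.allclose(theta, 0.2 * np.eye(4))

    def test_star_support_count(self):
        net = make_star_network(4, 1)
        off = net.precision - np.diag(np.diag(net.precision))
        assert (off != 0).sum() == 6  # 3 edges, symmetric

    @pytest.mark.parametrize("maker", ALL_MAKERS)
    def test_positive_definite_and_support_matches(self, maker):
        net = maker(11)
        eigvals = np.linalg.eigvalsh(net.precision)
        assert eigvals[0] > 0
        support = (np.abs(net.precision
                          - np.diag(np.diag(net.precision))) > 0)
        np.testing.assert_array_equal(support, net.adjacency.astype(bool))

    def test_asymmetric_rejected(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            precision_from_adjacency(adj)

    def test_hub_degree_ordering_invariant(self):
        for maker in ALL_MAKERS[:3]:  # star/hub/two_hub have strict hubs
            net = maker(23)
            deg = net.degrees
            hubs = [h - 1 for h in net.hub_ids]
            non_hubs = np.setdiff1d(np.arange(net.p), hubs)
            assert deg[hubs].min() > deg[non_hubs].max()


class TestSampling:
    def test_seeded_determinism(self):
        net = make_star_network(10, 2)
        a = sample_gaussian(net, 20, seed=9)
        b = sample_gaussian(net, 20, seed=9)
        assert a.equals(b)

    def test_large_sample_covariance_converges(self):
        net = make_star_network(10, 2)
        data = sample_gaussian(net, 50_000, seed=1)
        target = net.covariance()
        emp = np.cov(data.to_numpy(), rowvar=False)
        assert np.max(np.abs(emp - target)) < 0.05 * np.max(np.abs(target))

    def test_high_dimensional_allowed(self):
        net = make_star_network(120, 2)
        data = sample_gaussian(net, 2, seed=0)
        assert data.shape == (2, 120)

    def test_too_few_samples_rejected(self):
        net = make_star_network(6, 1)
        with pytest.raises(ValueError):
            sample_gaussian(net, 1)


def test_dispatch_and_unknown_model():
    net = make_network("star", 8, n_hubs=2)
    assert net.model_name == "star"
    with pytest.raises(ValueError, match="unknown model"):
        make_network("ring", 8)
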