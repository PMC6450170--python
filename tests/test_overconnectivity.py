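import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targettriage import overconnectivity as oc
from targettriage import synthetic_data
from targettriage.errors import DomainError
from targettriage.io import InteractionNetwork

from oracles import hypergeom_tail_comb, hypergeom_tail_enumerate


def net_from_pairs(pairs):
    net = InteractionNetwork()
    for s, t in pairs:
        net.add_edge(s, t)
    return net.validate()


class TestConnectivityStats:
    def make_case(self):
        """Focal gene F with 5 neighbors in an 11-node background
        (N=10 after excluding F), 4-gene experimental set fully inside
        the neighbor set -> Actual=4."""
        neighbors = [f"N{i}" for i in range(5)]
        others = [f"O{i}" for i in range(5)]
        net = net_from_pairs([("F", n) for n in neighbors])
        for o in others:
            net.add_node(o)
        background = set(neighbors) | set(others) | {"F"}
        deg_set = set(neighbors[:4])
        return net, deg_set, background

    def test_enumerated_example(self):
        net, deg_set, background = self.make_case()
        r = oc.connectivity_stats(net, deg_set, background, "F")
        assert (r.N, r.R, r.n, r.actual) == (10, 5, 4, 4)
        assert r.expected == pytest.approx(2.0, abs=1e-15)
        assert r.expected * r.N == pytest.approx(r.n * r.R, abs=1e-12)
        assert r.p == pytest.approx(5 / 210, abs=1e-12)
        assert r.p == pytest.approx(hypergeom_tail_enumerate(4, 10, 5, 4), abs=1e-12)

    def test_z_zero_when_actual_equals_expected(self):
        # focal gene adjacent to every background gene: R=N so any
        # n-subset has Actual = n = Expected exactly
        nodes = [f"N{i}" for i in range(8)]
        net = net_from_pairs([("F", n) for n in nodes])
        background = set(nodes) | {"F"}
        r = oc.connectivity_stats(net, set(nodes[:3]), background, "F")
        assert r.actual == r.expected
        assert r.z == 0.0

    def test_isolated_focal_gene(self):
        net = net_from_pairs([("A", "B")])
        net.add_node("F")
        r = oc.connectivity_stats(net, {"A"}, {"A", "B", "F"}, "F")
        assert (r.actual, r.R, r.expected, r.p) == (0, 0, 0.0, 1.0)

    def test_empty_deg_set_degenerate(self):
        net = net_from_pairs([("F", "A")])
        r = oc.connectivity_stats(net, set(), {"F", "A"}, "F")
        assert (r.actual, r.p) == (0, 1.0)

    def test_gene_outside_background_rejected(self):
        net = net_from_pairs([("A", "B")])
        with pytest.raises(DomainError):
            oc.connectivity_stats(net, {"A"}, {"A"}, "B")

    def test_permutation_oracle_random_graph(self):
        net, _ = synthetic_data.simulate_network(50, 6.0, [], set(), seed=13)
        background = set(net.nodes)
        rng = np.random.default_rng(99)
        nodes = sorted(net.nodes)
        deg_set = set(rng.choice(nodes, size=12, replace=False).tolist())
        focal = nodes[0]
        r = oc.connectivity_stats(net, deg_set, background, focal)
        # empirical null: 20,000 random n-subsets of the background
        pool = sorted(background - {focal})
        neighbors = net.neighbors(focal) & set(pool)
        draws = 20_000
        hits = 0
        for _ in range(draws):
            sub = rng.choice(pool, size=r.n, replace=False)
            if len(neighbors.intersection(sub)) >= r.actual:
                hits += 1
        p_emp = hits / draws
        se = np.sqrt(max(p_emp * (1 - p_emp), 1 / draws) / draws)
        assert abs(r.p - p_emp) <= 3 * se

    def test_p_monotone_in_actual(self):
        N, R, n = 40, 12, 10
        ps = [hypergeom_tail_comb(a, N, R, n) for a in range(n + 1)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_ratio_above_one_iff_z_positive(self):
        net, deg_set, background = self.make_case()
        r = oc.connectivity_stats(net, deg_set, background, "F")
        assert (r.z > 0) == (r.ratio is not None and r.ratio > 1)


class TestOverconnectedGenes:
    def test_star_hub_ranks_first(self):
        degs = [f"D{i}" for i in range(10)]
        filler = [f"X{i}" for i in range(89)]
        net = net_from_pairs([("HUB", d) for d in degs])
        for x in filler:
            net.add_node(x)
        background = set(degs) | set(filler) | {"HUB"}
        results = oc.overconnected_genes(net, set(degs), background,
                                         candidates=background)
        assert results[0].gene == "HUB"
        assert results[0].actual == 10

    def test_all_filtered_when_p_large(self):
        net = net_from_pairs([("A", "B"), ("C", "D")])
        results = oc.overconnected_genes(net, {"A"}, set(net.nodes), p_max=1e-9,
                                         candidates={"C"})
        assert results == []

    def test_planted_hub_recovery(self):
        genes = synthetic_data.default_gene_names(500)
        rng = np.random.default_rng(7)
        deg_genes = set(rng.choice(genes, size=40, replace=False).tolist())
        hub = sorted(deg_genes)[0]
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            net, _ = synthetic_data.simulate_network(
                500, 10.0, [(hub, 30)], deg_genes, seed=seed, genes=genes)
            results = oc.overconnected_genes(net, deg_genes, set(net.nodes))
            if results and results[0].gene == hub:
                wins += 1
        assert wins / n_seeds >= 0.95


class TestExpandNetwork:
    def test_chain_example(self, chain_network):
        sub = oc.expand_network(chain_network, {"B"})
        assert sub.nodes == {"A", "B", "C"}
        assert set(sub.edges) == {("A", "B"), ("B", "C")}

    def test_all_seeds_identity(self, chain_network):
        sub = oc.expand_network(chain_network, set(chain_network.nodes))
        assert sub.nodes == chain_network.nodes
        assert sub.edges == chain_network.edges

    def test_empty_seed_set(self, chain_network):
        sub = oc.expand_network(chain_network, set())
        assert sub.nodes == set() and sub.edges == {}

    def test_every_nonseed_touches_a_seed(self):
        for seed in range(100):
            net, _ = synthetic_data.simulate_network(40, 3.0, [], set(), seed=seed)
            rng = np.random.default_rng(seed)
            seeds = set(rng.choice(sorted(net.nodes), size=4, replace=False).tolist())
            sub = oc.expand_network(net, seeds)
            for node in sub.nodes - seeds:
                assert sub.neighbors(node) & seeds


class TestHubRank:
    def test_star_center_first(self):
        net = net_from_pairs([("HUB", f"L{i}") for i in range(5)])
        ranked = oc.hub_rank(net)
        assert ranked[0] == ("HUB", 5)

    def test_alphabetical_tie(self):
        net = net_from_pairs([("B", "A")])
        assert oc.hub_rank(net) == [("A", 1), ("B", 1)]

    def test_handshake_on_random_graphs(self):
        for seed in range(10):
            net, _ = synthetic_data.simulate_network(30, 4.0, [], set(), seed=seed)
            total = sum(d for _g, d in oc.hub_rank(net))
            undirected_pairs = {tuple(sorted(e)) for e in net.edges}
            assert total == 2 * len(undirected_pairs)


def test_configuration_model_calibration():
    """Degree-preserving rewiring must not produce spuriously tiny
    over-connectivity p-values more often than the discrete
    super-uniform null allows."""
    import networkx as nx

    genes = synthetic_data.default_gene_names(300)
    rng = np.random.default_rng(21)
    deg_genes = set(rng.choice(genes, size=30, replace=False).tolist())
    base, _ = synthetic_data.simulate_network(300, 8.0, [], deg_genes, seed=21, genes=genes)
    g = nx.Graph()
    g.add_nodes_from(base.nodes)
    g.add_edges_from({tuple(sorted(e)) for e in base.edges})
    threshold = 1 / 20_000
    n_tests = 0
    n_below = 0
    for seed in range(20):
        shuffled = g.copy()
        nx.double_edge_swap(shuffled, nswap=2 * shuffled.number_of_edges(),
                            max_tries=10 ** 6, seed=seed)
        net = InteractionNetwork()
        for node in shuffled.nodes:
            net.add_node(node)
        for s, t in shuffled.edges:
            net.add_edge(s, t)
        results = oc.overconnected_genes(net, deg_genes, set(net.nodes), p_max=1.0)
        n_tests += len(results)
        n_below += sum(1 for r in results if r.p < threshold)
    from scipy import stats
    limit = stats.poisson.ppf(0.999, n_tests * threshold)
    assert n_below <= limit


def test_connectivity_tsv_round_trip(tmp_path):
    r = oc.ConnectivityResult("CCR2", 10, 40, 20, 200, 4.0, 2.5, 3.2, 0.002)
    oc.write_connectivity([r], tmp_path / "c.tsv")
    (back,) = oc.read_connectivity(tmp_path / "c.tsv")
    assert back == r
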