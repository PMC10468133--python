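"""Consensus intersection, Fisher agreement, maximal-clique enumeration."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats

from cofrac.cliques import (fisher_exact_two_sided, intersect_networks,
                            maximal_cliques, method_agreement,
                            summarize_cliques)
from cofrac.errors import InputError
from cofrac.networks import CoelutionNetwork


def net_from_edges(edges, nodes, method="pcc", threshold=0.5):
    return CoelutionNetwork(
        nodes=tuple(sorted(nodes)),
        edges={tuple(sorted(e)): 0.9 for e in edges},
        method=method, threshold=threshold)


def random_net(rng, nodes, p, method):
    edges = [e for e in itertools.combinations(sorted(nodes), 2)
             if rng.random() < p]
    return net_from_edges(edges, nodes, method=method)


def brute_force_maximal_cliques(nodes, edge_set, min_size):
    """Subset-enumeration oracle: feasible only for ~12 nodes."""
    nodes = sorted(nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(tuple(sorted(p)) in edge_set
                   for p in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = [c for c in cliques
               if not any(c < other for other in cliques)]
    return sorted((tuple(sorted(c)) for c in maximal if len(c) >= min_size),
                  key=lambda c: (-len(c), c))


class TestMaximalCliques:
    def test_triangle(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")], "abc")
        assert maximal_cliques(net).cliques == (("a", "b", "c"),)

    def test_path_excludes_supersets(self):
        net = net_from_edges([("a", "b"), ("b", "c")], "abc")
        assert maximal_cliques(net).cliques == (("a", "b"), ("b", "c"))

    def test_matches_bruteforce_on_random_graphs(self, rng):
        for trial in range(12):
            n = int(rng.integers(4, 13))
            nodes = [f"n{i}" for i in range(n)]
            net = random_net(rng, nodes, p=0.4, method="pcc")
            ours = maximal_cliques(net, min_size=2).cliques
            oracle = tuple(brute_force_maximal_cliques(
                nodes, set(net.edges), min_size=2))
            assert ours == oracle

    def test_matches_networkx(self, rng):
        import networkx as nx

        nodes = [f"n{i}" for i in range(20)]
        net = random_net(rng, nodes, p=0.3, method="pcc")
        ours = {frozenset(c) for c in maximal_cliques(net, min_size=1).cliques}
        theirs = {frozenset(c) for c in nx.find_cliques(net.to_networkx())}
        assert ours == theirs

    def test_every_clique_is_maximal(self, rng):
        nodes = [f"n{i}" for i in range(15)]
        net = random_net(rng, nodes, p=0.35, method="pcc")
        adj = {v: set() for v in nodes}
        for a, b in net.edges:
            adj[a].add(b)
            adj[b].add(a)
        for clique in maximal_cliques(net).cliques:
            members = set(clique)
            for candidate in set(nodes) - members:
                assert not members <= adj[candidate]


class TestIntersect:
    def test_identical_networks(self, rng):
        nodes = [f"n{i}" for i in range(8)]
        net = random_net(rng, nodes, 0.4, "pcc")
        other = CoelutionNetwork(nodes=net.nodes, edges=dict(net.edges),
                                 method="prince", threshold=0.5)
        out = intersect_networks([net, other])
        assert set(out.edges) == set(net.edges)

    def test_three_way_set_logic_oracle(self, rng):
        nodes = [f"n{i}" for i in range(10)]
        nets = [random_net(rng, nodes, 0.4, m)
                for m in ("pcc", "local_spearman", "prince")]
        out = intersect_networks(nets)
        sets = [set(n.edges) for n in nets]
        assert set(out.edges) == sets[0] & sets[1] & sets[2]
        # intersection contained in every input
        for s in sets:
            assert set(out.edges) <= s
        # Venn regions partition the union
        assert sum(out.venn.values()) == len(sets[0] | sets[1] | sets[2])

    def test_mismatched_universe_rejected(self, rng):
        n1 = net_from_edges([("a", "b")], "ab")
        n2 = net_from_edges([("a", "c")], "ac", method="prince")
        with pytest.raises(InputError):
            intersect_networks([n1, n2])


class TestFisher:
    def test_documented_table(self):
        p, odds = fisher_exact_two_sided(10, 2, 3, 40)
        assert odds == pytest.approx(66.6667, rel=1e-4)
        # independent tail enumeration with exact binomial weights
        r1, r2, c1 = 12, 43, 13
        weights = {a: math.comb(r1, a) * math.comb(r2, c1 - a)
                   for a in range(max(0, c1 - r2), min(r1, c1) + 1)}
        expect = sum(w for w in weights.values() if w <= weights[10]) \
            / math.comb(55, 13)
        assert p == pytest.approx(expect, abs=1e-15)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            if a + b + c + d == 0:
                continue
            p, _ = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
            ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert p == pytest.approx(ref, abs=1e-9)

    def test_haldane_correction_on_zero_cell(self):
        _, odds = fisher_exact_two_sided(5, 0, 2, 10)
        assert odds == pytest.approx((5.5 * 10.5) / (0.5 * 2.5))

    def test_perfect_agreement_minimal_p(self, rng):
        nodes = [f"n{i}" for i in range(12)]
        net = random_net(rng, nodes, 0.4, "pcc")
        twin = CoelutionNetwork(nodes=net.nodes, edges=dict(net.edges),
                                method="prince", threshold=0.5)
        res = method_agreement(net, twin)
        assert res.table[0, 1] == 0 and res.table[1, 0] == 0
        # observed table is the most extreme one under its margins: the only
        # hypergeometric terms that can enter the two-sided sum are the
        # (weight-1) extremes, so p is at most 2 / C(n_pairs, k)
        n_pairs = len(nodes) * (len(nodes) - 1) // 2
        k = int(res.table[0, 0])
        assert res.p_value <= 2.0 / math.comb(n_pairs, k) + 1e-15
        assert res.significant

    def test_independent_edge_sets_null_odds_ratio(self, rng):
        nodes = [f"n{i}" for i in range(40)]
        odds = []
        for _ in range(500):
            pairs = list(itertools.combinations(nodes, 2))
            mask_a = rng.random(len(pairs)) < 0.3
            mask_b = rng.random(len(pairs)) < 0.3
            a = int((mask_a & mask_b).sum())
            b = int((mask_a & ~mask_b).sum())
            c = int((~mask_a & mask_b).sum())
            d = int((~mask_a & ~mask_b).sum())
            odds.append(fisher_exact_two_sided(a, b, c, d)[1])
        assert 0.8 <= float(np.median(odds)) <= 1.25

    def test_counts_cover_pair_universe(self, rng):
        nodes = [f"n{i}" for i in range(15)]
        n1 = random_net(rng, nodes, 0.3, "pcc")
        n2 = random_net(rng, nodes, 0.3, "prince")
        res = method_agreement(n1, n2)
        assert res.table.sum() == len(nodes) * (len(nodes) - 1) // 2


class TestSummarize:
    def test_size_histogram(self):
        edges = [("a", "b"), ("c", "d"), ("e", "f"), ("e", "g"), ("f", "g"),
                 ("h", "i"), ("h", "j"), ("h", "k"), ("h", "l"),
                 ("i", "j"), ("i", "k"), ("i", "l"),
                 ("j", "k"), ("j", "l"), ("k", "l")]
        net = net_from_edges(edges, "abcdefghijkl")
        summary = summarize_cliques(maximal_cliques(net))
        assert summary.size_histogram == {2: 2, 3: 1, 5: 1}

    def test_empty_network(self):
        net = net_from_edges([], "ab")
        summary = summarize_cliques(maximal_cliques(net))
        assert summary.size_histogram == {}
        assert len(summary.table) == 0

    def test_reference_provenance(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")], "abc")
        summary = summarize_cliques(maximal_cliques(net), reference_ids={"a"})
        row = summary.table.iloc[0]
        assert row["n_reference_known"] == 1
        assert row["n_study_unique"] == 2
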