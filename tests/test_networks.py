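"""Co-elution scoring: Pearson, windowed Spearman, classifier networks."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cofrac.errors import InputError
from cofrac.networks import (CoelutionNetwork, ReferenceComplexSet,
                             collapse_local_networks, local_spearman_networks,
                             pcc_network, prince_scores)
from cofrac.proteome import ProteinProfileMatrix


def random_matrix(rng, n_proteins, n_fractions=28, first=23):
    vals = rng.uniform(0.0, 1.0, size=(n_proteins, n_fractions))
    vals = vals / vals.max(axis=1, keepdims=True)
    return ProteinProfileMatrix(pd.DataFrame(
        vals, index=[f"P{i:03d}" for i in range(n_proteins)],
        columns=range(first, first + n_fractions)), normalized=True)


class TestPccNetwork:
    def test_edges_match_bruteforce_pearson(self, rng):
        m = random_matrix(rng, 8)
        net = pcc_network(m, threshold=0.2)
        for a, b in itertools.combinations(m.proteins, 2):
            r = stats.pearsonr(m.values.loc[a], m.values.loc[b]).statistic
            assert net.has_edge(a, b) == (r > 0.2)
            if net.has_edge(a, b):
                assert net.score(a, b) == pytest.approx(r, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 17])
    def test_pair_count_identity(self, rng, n):
        net = pcc_network(random_matrix(rng, n))
        assert net.n_pairs_evaluated == n * (n - 1) // 2

    def test_identical_profiles_edge(self, rng):
        vals = rng.uniform(0, 1, size=12)
        vals = vals / vals.max()
        m = ProteinProfileMatrix(pd.DataFrame(
            [vals, vals], index=["A", "B"], columns=range(23, 35)),
            normalized=True)
        net = pcc_network(m)
        assert net.has_edge("A", "B")
        assert net.score("A", "B") == pytest.approx(1.0)

    def test_flat_profile_skipped(self, rng):
        m = random_matrix(rng, 3)
        vals = m.values.copy()
        vals.loc["P000"] = 1.0  # constant row: undefined correlation
        net = pcc_network(ProteinProfileMatrix(vals, normalized=True))
        assert net.n_pairs_skipped == 2
        assert not any("P000" in e for e in net.edges)

    def test_rescaling_invariance(self, rng):
        # correlations are scale-free per protein
        m = random_matrix(rng, 6)
        scaled = ProteinProfileMatrix(
            m.values.mul(rng.uniform(0.1, 1.0, size=6), axis=0),
            normalized=True)
        assert set(pcc_network(m, 0.3).edges) == set(
            pcc_network(scaled, 0.3).edges)


class TestLocalSpearman:
    def test_window_count_for_28_fractions(self, rng):
        nets = local_spearman_networks(random_matrix(rng, 5))
        assert len(nets) == 24
        assert nets[0].window_id == 25 and nets[-1].window_id == 48

    def test_single_window_boundary(self, rng):
        m = random_matrix(rng, 4, n_fractions=5)
        nets = local_spearman_networks(m)
        assert len(nets) == 1

    def test_edges_match_bruteforce_spearman(self, rng):
        m = random_matrix(rng, 6)
        nets = local_spearman_networks(m, threshold=0.5)
        arr = m.values
        for net in nets:
            center = net.window_id
            cols = [c for c in arr.columns if abs(c - center) <= 2]
            for a, b in itertools.combinations(m.proteins, 2):
                rho = stats.spearmanr(arr.loc[a, cols], arr.loc[b, cols]).statistic
                assert net.has_edge(a, b) == (rho > 0.5)

    def test_too_few_fractions(self, rng):
        with pytest.raises(InputError):
            local_spearman_networks(random_matrix(rng, 4, n_fractions=4))


class TestCollapse:
    def _net(self, edges, window, nodes=("A", "B", "C")):
        return CoelutionNetwork(nodes=nodes, edges=edges,
                                method="local_spearman", threshold=0.5,
                                window_id=window)

    def test_single_network_identity(self):
        net = self._net({("A", "B"): 0.9}, 25)
        out = collapse_local_networks([net])
        assert set(out.edges) == {("A", "B")}

    def test_disjoint_union_and_max_score(self):
        n1 = self._net({("A", "B"): 0.9}, 25)
        n2 = self._net({("B", "C"): 0.8, ("A", "B"): 0.95}, 26)
        out = collapse_local_networks([n1, n2])
        assert set(out.edges) == {("A", "B"), ("B", "C")}
        assert out.edges[("A", "B")] == pytest.approx(0.95)
        assert out.edge_windows[("A", "B")] == (25, 26)

    def test_union_matches_set_oracle(self, rng):
        m = random_matrix(rng, 7)
        nets = local_spearman_networks(m, threshold=0.4)
        out = collapse_local_networks(nets)
        oracle = set().union(*[set(n.edges) for n in nets])
        assert set(out.edges) == oracle

    def test_mixed_methods_rejected(self):
        n1 = self._net({}, 25)
        n2 = CoelutionNetwork(nodes=("A", "B", "C"), edges={}, method="pcc",
                              threshold=0.5)
        with pytest.raises(InputError):
            collapse_local_networks([n1, n2])


def planted_matrix(rng, n_complex_members=12, n_background=24):
    """Three planted 4-member complexes with shared profiles plus noise."""
    fractions = list(range(23, 51))
    rows, names, complexes = [], [], {}
    for ci in range(3):
        mu = 27 + 8 * ci
        base = np.exp(-0.5 * ((np.array(fractions) - mu) / 1.2) ** 2)
        members = []
        for j in range(4):
            name = f"C{ci}_{j}"
            rows.append(base * rng.lognormal(0, 0.05, size=len(fractions)))
            names.append(name)
            members.append(name)
        complexes[f"cpx{ci}"] = frozenset(members)
    for i in range(n_background):
        mu = rng.uniform(24, 49)
        rows.append(np.exp(-0.5 * ((np.array(fractions) - mu) / 1.5) ** 2)
                    * rng.lognormal(0, 0.05, size=len(fractions)))
        names.append(f"B{i}")
    vals = np.vstack(rows)
    vals = vals / vals.max(axis=1, keepdims=True)
    m = ProteinProfileMatrix(pd.DataFrame(vals, index=names, columns=fractions),
                             normalized=True)
    return m, ReferenceComplexSet(complexes=complexes)


class TestPrince:
    def test_identical_beats_orthogonal(self, rng):
        m, ref = planted_matrix(rng)
        net = prince_scores(m, ref, threshold=0.0001, seed=17)
        same = net.score("C0_0", "C0_1")          # co-eluting pair
        other = net.edges.get(("C0_0", "C2_0"), 0.0)  # different position
        assert same > other

    def test_planted_pairs_rank_high(self, rng):
        m, ref = planted_matrix(rng)
        net = prince_scores(m, ref, threshold=1e-12, seed=17)
        pos = [net.score(a, b) for a, b in ref.co_member_pairs(m.proteins)]
        neg_pairs = [p for p in itertools.combinations(sorted(m.proteins), 2)
                     if p not in ref.co_member_pairs(m.proteins)]
        neg = [net.edges.get(p, 0.0) for p in neg_pairs]
        cutoff = np.percentile(neg, 90)
        assert np.mean([s > cutoff for s in pos]) >= 0.9

    def test_deterministic_given_seed(self, rng):
        m, ref = planted_matrix(rng)
        n1 = prince_scores(m, ref, seed=17)
        n2 = prince_scores(m, ref, seed=17)
        assert n1.edges == n2.edges

    def test_no_reference_pairs_error(self, rng):
        m, _ = planted_matrix(rng)
        ref = ReferenceComplexSet(complexes={"x": frozenset({"ZZ1", "ZZ2"})})
        with pytest.raises(InputError):
            prince_scores(m, ref)


def test_edge_list_roundtrip(tmp_path, rng):
    m = random_matrix(rng, 9)
    net = pcc_network(m, threshold=0.2)
    path = tmp_path / "edges.tsv"
    net.to_tsv(path)
    back = CoelutionNetwork.from_tsv(path, net.nodes, threshold=0.2)
    assert set(back.edges) == set(net.edges)
    for pair, score in net.edges.items():
        assert back.edges[pair] == pytest.approx(score, abs=1e-12)
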