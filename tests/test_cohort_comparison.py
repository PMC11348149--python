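import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aopmoa.coexpression import CoexpressionNetwork
from aopmoa.cohort_comparison import (
    NetworkDistanceMatrix,
    cluster_moa_networks,
    combine_edge_pvalues,
    consensus_cluster,
    edge_distance_matrix,
    edge_set_enrichment,
    linkage_to_newick,
    moa_distance_matrix,
    overrepresented_edges,
    read_gmt,
)
from aopmoa.errors import ParameterError
from aopmoa.moa_builder import MOANetwork


def _net(edges, exposure_id):
    g = nx.Graph()
    g.add_edges_from(edges)
    for n in g.nodes():
        g.nodes[n]["logfc"] = 0.0
    return CoexpressionNetwork(g, exposure_id=exposure_id)


def _moa(nodes, edges, exposure_id="m"):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return MOANetwork(graph=g, exposure_id=exposure_id)


class TestEdgeDistanceMatrix:
    def test_identical_networks_distance_zero(self):
        a = _net([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")], "n1")
        b = _net([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")], "n2")
        dist = edge_distance_matrix([a, b])
        assert dist.matrix[0, 1] == pytest.approx(0.0)

    def test_disjoint_networks(self):
        a = _net([("a", "b"), ("c", "d")], "n1")
        b = _net([("e", "f"), ("g", "h")], "n2")
        dist = edge_distance_matrix([a, b])
        assert dist.components["jaccard_dist"][0, 1] == pytest.approx(1.0)
        # universe = 4 edges, all mismatched
        assert dist.components["hamming"][0, 1] == pytest.approx(1.0)
        assert np.isnan(dist.components["kendall"][0, 1])

    def test_matches_brute_force_oracle(self):
        nets = [
            _net([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e")], "n1"),
            _net([("a", "b"), ("b", "c"), ("c", "d"), ("d", "f"), ("a", "c")], "n2"),
            _net([("a", "b"), ("x", "y"), ("y", "z")], "n3"),
        ]
        dist = edge_distance_matrix(nets)
        edge_sets = [frozenset(frozenset(e) for e in n.graph.edges()) for n in nets]
        universe = frozenset().union(*edge_sets)
        for i, j in itertools.combinations(range(3), 2):
            ei, ej = edge_sets[i], edge_sets[j]
            jac = len(ei & ej) / len(ei | ej)
            mism = sum(1 for e in universe if (e in ei) != (e in ej))
            expected = {
                "jaccard_sim": 1 - jac,
                "jaccard_dist": 1 - jac,
                "hamming": mism / len(universe),
                "smc": 1 - (len(universe) - mism) / len(universe),
            }
            for name, val in expected.items():
                assert dist.components[name][i, j] == pytest.approx(val), name
            common = sorted(ei & ej, key=lambda e: tuple(sorted(e)))
            if len(common) >= 3:
                bi = nx.edge_betweenness_centrality(nets[i].graph)
                bj = nx.edge_betweenness_centrality(nets[j].graph)
                bi = {frozenset(k): v for k, v in bi.items()}
                bj = {frozenset(k): v for k, v in bj.items()}
                tau = stats.kendalltau(
                    [bi[e] for e in common], [bj[e] for e in common]
                ).statistic
                expected["kendall"] = (1 - tau) / 2
                assert dist.components["kendall"][i, j] == pytest.approx(expected["kendall"])
            vals = [v for v in expected.values() if np.isfinite(v)]
            assert dist.matrix[i, j] == pytest.approx(np.mean(vals))

    def test_needs_two_networks(self):
        with pytest.raises(ParameterError):
            edge_distance_matrix([_net([("a", "b")], "n1")])

    def test_premetric_properties(self):
        nets = [
            _net([("a", "b"), ("b", "c")], "n1"),
            _net([("a", "b"), ("c", "d")], "n2"),
            _net([("x", "y")], "n3"),
        ]
        dist = edge_distance_matrix(nets)
        assert np.allclose(dist.matrix, dist.matrix.T)
        assert np.allclose(np.diag(dist.matrix), 0.0)
        assert (dist.matrix >= 0).all()


def _blob_distance_matrix(n_per=4, gap=0.9, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    d = np.full((n, n), gap)
    for i, j in itertools.product(range(n), range(n)):
        if (i < n_per) == (j < n_per):
            d[i, j] = noise
    d = (d + d.T) / 2
    d += rng.uniform(0, 0.01, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return NetworkDistanceMatrix(ids=[f"e{i}" for i in range(n)], matrix=d)


class TestConsensusCluster:
    def test_recovers_two_blobs(self):
        dist = _blob_distance_matrix()
        labels = consensus_cluster(dist, k=2, seed=0)
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]

    def test_deterministic_under_seed(self):
        dist = _blob_distance_matrix(seed=3)
        a = consensus_cluster(dist, k=2, seed=11)
        b = consensus_cluster(dist, k=2, seed=11)
        assert np.array_equal(a, b)

    def test_k_equals_n_singletons(self):
        dist = _blob_distance_matrix()
        labels = consensus_cluster(dist, k=8, seed=0)
        assert len(set(labels)) == 8

    def test_k_too_large(self):
        with pytest.raises(ParameterError):
            consensus_cluster(_blob_distance_matrix(), k=9)


class TestClusterMoaNetworks:
    def test_duplicate_moas_merge_first(self):
        a = _moa("abc", [("a", "b")], "m1")
        b = _moa("abc", [("a", "b")], "m2")
        c = _moa("xyz", [("x", "y"), ("y", "z")], "m3")
        z, labels, ids = cluster_moa_networks([a, b, c], k=2)
        first_merge = z[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == pytest.approx(0.0)
        assert labels[0] == labels[1] != labels[2]

    def test_family_separation(self):
        fam1 = [
            _moa([f"A{i}" for i in range(9)] + ["S"], [(f"A{i}", f"A{i+1}") for i in range(8)], f"f1_{j}")
            for j in range(3)
        ]
        fam2 = [
            _moa([f"B{i}" for i in range(9)] + ["S"], [(f"B{i}", f"B{i+1}") for i in range(8)], f"f2_{j}")
            for j in range(3)
        ]
        _, labels, ids = cluster_moa_networks(fam1 + fam2, k=2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_identical_moas_zero_heights(self):
        moas = [_moa("ab", [("a", "b")], f"m{i}") for i in range(4)]
        z, _, _ = cluster_moa_networks([*moas], k=2)
        assert np.allclose(z[:, 2], 0.0)

    def test_distance_is_one_minus_mean_jaccard(self):
        a = _moa(["a", "b", "c"], [("a", "b")], "m1")
        b = _moa(["a", "b", "d"], [("a", "b"), ("b", "d")], "m2")
        dist = moa_distance_matrix([a, b])
        node_j = 2 / 4
        edge_j = 1 / 2
        assert dist.matrix[0, 1] == pytest.approx(1 - (node_j + edge_j) / 2)

    def test_needs_two(self):
        with pytest.raises(ParameterError):
            cluster_moa_networks([_moa("ab", [("a", "b")])], k=2)


def hypergeom_tail_oracle(in_cluster, total, in_total, cluster_size):
    """Exhaustive enumeration of the hypergeometric upper tail."""
    num = sum(
        math.comb(in_total, k) * math.comb(total - in_total, cluster_size - k)
        for k in range(in_cluster, min(in_total, cluster_size) + 1)
    )
    return num / math.comb(total, cluster_size)


class TestOverrepresentedEdges:
    def _collection(self):
        # edge ab in all 4 cluster networks minus one; others sporadic
        nets = []
        for i in range(4):
            edges = [("a", "b")] if i < 3 else [("c", "d")]
            nets.append(_net(edges + [("e", f"f{i}")], f"c{i}"))
        for i in range(6):
            nets.append(_net([("x", f"y{i}")], f"o{i}"))
        return nets

    def test_matches_enumeration_example(self):
        # edge in 3 of 4 cluster networks and 3 of 10 total -> p = 1/30
        out = overrepresented_edges(self._collection(), {f"c{i}" for i in range(4)}, alpha=1.0)
        row = out[(out["gene_a"] == "a") & (out["gene_b"] == "b")].iloc[0]
        assert row["p"] == pytest.approx(1 / 30)
        assert row["p"] == pytest.approx(hypergeom_tail_oracle(3, 10, 3, 4))

    def test_saturated_edge_p_one(self):
        nets = [_net([("a", "b")], f"n{i}") for i in range(6)]
        out = overrepresented_edges(nets, {"n0", "n1"}, alpha=1.0)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_edge_absent_from_cluster_not_tested(self):
        out = overrepresented_edges(self._collection(), {f"c{i}" for i in range(4)}, alpha=1.0)
        assert not ((out["gene_a"] == "x")).any()

    def test_cluster_must_be_proper_subset(self):
        nets = [_net([("a", "b")], f"n{i}") for i in range(3)]
        with pytest.raises(ParameterError):
            overrepresented_edges(nets, {"n0", "n1", "n2"})

    def test_exhaustive_enumeration_small_collections(self):
        # all configurations with <= 8 networks against the pmf oracle
        for total in range(3, 9):
            for cluster_size in range(1, total):
                for in_total in range(1, total + 1):
                    for in_cluster in range(1, min(cluster_size, in_total) + 1):
                        p = float(
                            stats.hypergeom.sf(in_cluster - 1, total, in_total, cluster_size)
                        )
                        oracle = hypergeom_tail_oracle(in_cluster, total, in_total, cluster_size)
                        assert p == pytest.approx(oracle, rel=1e-10)


class TestEdgeSetEnrichment:
    def _edges(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            rows.append((f"g{2*i}", f"g{2*i+1}", float(rng.uniform(1e-6, 1))))
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "p"])
        return df.sort_values("p").reset_index(drop=True)

    def test_all_hits_es_one(self):
        edges = self._edges(10)
        genes = set(edges["gene_a"]) | set(edges["gene_b"])
        out = edge_set_enrichment(edges, {"P": genes}, n_perm=20, seed=0)
        assert out.loc[0, "es"] == pytest.approx(1.0)

    def test_p_perm_lower_bound(self):
        edges = self._edges(40)
        top_genes = set(edges.head(8)[["gene_a", "gene_b"]].to_numpy().ravel())
        out = edge_set_enrichment(edges, {"TOP": top_genes}, n_perm=50, seed=1)
        # hits occupy the very top of the ranking: no permutation can beat it
        assert out.loc[0, "p_perm"] == pytest.approx(1 / 51)

    def test_small_pathway_skipped(self):
        edges = self._edges(10)
        out = edge_set_enrichment(edges, {"tiny": {"g0"}}, n_perm=20, seed=0)
        assert out.empty

    def test_no_hit_pathway_p_one(self):
        edges = self._edges(10)
        out = edge_set_enrichment(edges, {"none": {"zz1", "zz2"}}, n_perm=20, seed=0)
        assert out.loc[0, "es"] == 0.0 and out.loc[0, "p_perm"] == 1.0

    def test_warns_low_n_perm(self):
        edges = self._edges(10)
        with pytest.warns(UserWarning, match="n_perm"):
            edge_set_enrichment(edges, {"P": {"g0", "g1"}}, n_perm=5, seed=0)


class TestCombinePvalues:
    def test_all_ones(self):
        assert combine_edge_pvalues([1.0, 1.0]) == pytest.approx(1.0)

    def test_half_half_chi2_oracle(self):
        # X = -2 ln(0.5) * 2 = 2.7726; upper tail of chi2 with 4 df
        expected = float(stats.chi2.sf(-2 * 2 * math.log(0.5), 4))
        assert expected == pytest.approx(0.5966, abs=1e-4)
        assert combine_edge_pvalues([0.5, 0.5]) == pytest.approx(expected, abs=1e-12)

    def test_single_p_identity(self):
        assert combine_edge_pvalues([0.37]) == pytest.approx(0.37, abs=1e-12)

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            p = combine_edge_pvalues([0.0, 0.5])
        assert 0 <= p < 0.5

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            combine_edge_pvalues([])


class TestIO:
    def test_newick_roundtrip_leaves(self):
        moas = [
            _moa("ab", [("a", "b")], "m1"),
            _moa("ab", [("a", "b")], "m2"),
            _moa("xy", [("x", "y")], "m3"),
        ]
        z, _, ids = cluster_moa_networks(moas, k=2)
        newick = linkage_to_newick(z, ids)
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["m1", "m2", "m3"]

    def test_read_gmt(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc\tg1\tg2\nS2\tdesc\tg3\tg4\tg5\n")
        sets = read_gmt(path)
        assert sets == {"S1": {"g1", "g2"}, "S2": {"g3", "g4", "g5"}}
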