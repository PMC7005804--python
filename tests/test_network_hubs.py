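import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methnet import network_hubs as nh
from methnet.io_formats import PathwayDB, PPIEdgeTable


def _edges(pairs, score=0.9, coexp=0.5):
    rows = [(a, b, s if s is not None else score, coexp)
            for a, b, s in ((p[0], p[1], p[2] if len(p) > 2 else None) for p in pairs)]
    return PPIEdgeTable(pd.DataFrame(rows, columns=["gene_a", "gene_b",
                                                    "combined_score", "coexpression"]))


# ---------------------------------------------------------------------------
# build_graph
# ---------------------------------------------------------------------------


class TestBuildGraph:
    def test_threshold_zero_keeps_all(self):
        t = _edges([("A", "B"), ("B", "C", 0.2)])
        g = nh.build_graph(t, score_threshold=0.0)
        assert set(g.edges) == {("A", "B"), ("B", "C")}

    def test_min_degree_3_on_path_graph_empty(self):
        t = _edges([(f"n{i}", f"n{i+1}") for i in range(5)])
        with pytest.warns(UserWarning, match="empty"):
            g = nh.build_graph(t, min_degree=3)
        assert g.number_of_nodes() == 0

    def test_iterative_filter_matches_brute_force_fixed_point(self, rng):
        for _ in range(10):
            base = nx.gnp_random_graph(30, 0.12, seed=int(rng.integers(1e6)))
            t = _edges([(f"n{a}", f"n{b}") for a, b in base.edges])
            g = nh.build_graph(t, min_degree=3)
            # brute force: repeatedly remove any node with degree < 3
            h = nx.Graph([(f"n{a}", f"n{b}") for a, b in base.edges])
            changed = True
            while changed:
                changed = False
                for v in list(h.nodes):
                    if h.degree(v) < 3:
                        h.remove_node(v)
                        changed = True
            assert {frozenset(e) for e in g.edges} == {frozenset(e) for e in h.edges}


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------


def brute_force_centralities(graph):
    """Definition-level centralities via explicit all-pairs path enumeration."""
    out = {}
    for v in graph.nodes:
        comp = nx.node_connected_component(graph, v)
        sub = graph.subgraph(comp)
        nc = len(comp)
        degree = graph.degree(v)
        clustering = nx.clustering(graph, v)
        if nc == 1:
            out[v] = dict(degree=degree, betweenness=0.0, closeness=0.0,
                          clustering_coefficient=clustering, avg_shortest_path=0.0,
                          stress=0.0, radiality=0.0)
            continue
        dists = dict(nx.shortest_path_length(sub, v))
        total = sum(dists.values())
        diam = max(d for s in comp for d in dict(nx.shortest_path_length(sub, s)).values())
        betw = 0.0
        stress = 0.0
        for s, t in itertools.combinations([n for n in comp if n != v], 2):
            paths = list(nx.all_shortest_paths(sub, s, t))
            through = [p for p in paths if v in p]
            if through:
                betw += len(through) / len(paths)
                stress += len(through)
        out[v] = dict(
            degree=degree, betweenness=betw, closeness=(nc - 1) / total,
            clustering_coefficient=clustering, avg_shortest_path=total / (nc - 1),
            stress=stress,
            radiality=sum(diam + 1 - d for u, d in dists.items() if u != v) / (nc - 1),
        )
    return out


class TestCentralities:
    def test_star_closed_form(self):
        # K_{1,5}: center betweenness = (n-1)(n-2)/2 = 10
        t = _edges([("hub", f"leaf{i}") for i in range(5)])
        c = nh.centralities(nh.build_graph(t, 0.0))
        assert c.loc["hub", "degree"] == 5
        assert c.loc["hub", "betweenness"] == pytest.approx(10.0)
        assert c.loc["hub", "clustering_coefficient"] == 0.0
        assert c.loc["leaf0", "betweenness"] == pytest.approx(0.0)
        assert c.loc["hub", "stress"] == pytest.approx(10.0)

    def test_triangle(self):
        t = _edges([("A", "B"), ("B", "C"), ("A", "C")])
        c = nh.centralities(nh.build_graph(t, 0.0))
        assert (c["clustering_coefficient"] == 1.0).all()
        assert (c["betweenness"] == 0.0).all()
        assert (c["avg_shortest_path"] == 1.0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_graphs(self, seed):
        base = nx.gnp_random_graph(12, 0.3, seed=seed)
        graph = nx.relabel_nodes(base, {i: f"n{i}" for i in base.nodes})
        c = nh.centralities(graph)
        expected = brute_force_centralities(graph)
        for v, exp in expected.items():
            for key, val in exp.items():
                assert c.loc[v, key] == pytest.approx(val), (v, key)

    def test_disconnected_components_handled(self):
        t = _edges([("A", "B"), ("C", "D"), ("D", "E")])
        c = nh.centralities(nh.build_graph(t, 0.0))
        assert c.loc["A", "closeness"] == pytest.approx(1.0)
        assert c.loc["D", "closeness"] == pytest.approx(2 / 2)

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError, match="empty"):
            nh.centralities(nx.Graph())


# ---------------------------------------------------------------------------
# kmeans_hub_clusters
# ---------------------------------------------------------------------------


def _blob_table(rng, centers, n_per, spread=0.05):
    rows = []
    for ci, center in enumerate(centers):
        for j in range(n_per):
            rows.append([c + rng.normal(0, spread) for c in center])
    idx = [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx, columns=list(nh.DEFAULT_FEATURES))


class TestKmeansHubClusters:
    def test_separable_blobs_high_jaccard(self, rng):
        table = _blob_table(rng, [(0, 0, 0, 0), (5, 5, 5, 5)], 20)
        hc = nh.kmeans_hub_clusters(table, k=2, seed=0, n_boot=50)
        assert (hc.jaccard >= 0.95).all()
        assert hc.stable.all()

    def test_identical_rows_degenerate_warns(self):
        table = pd.DataFrame(np.ones((10, 4)), columns=list(nh.DEFAULT_FEATURES))
        with pytest.warns(UserWarning, match="degenerate"):
            hc = nh.kmeans_hub_clusters(table, k=2, n_boot=10)
        assert hc.degenerate
        assert np.isnan(hc.jaccard).all()

    def test_stability_threshold_semantics(self, rng):
        # stable iff mean Jaccard >= 0.75
        table = _blob_table(rng, [(0, 0, 0, 0), (5, 5, 5, 5), (10, 0, 5, 2)], 15)
        hc = nh.kmeans_hub_clusters(table, k=3, seed=1, n_boot=50)
        assert (hc.stable == (hc.jaccard >= 0.75)).all()

    def test_k_larger_than_n_errors(self, rng):
        table = _blob_table(rng, [(0, 0, 0, 0)], 3)
        with pytest.raises(ValueError, match="exceeds"):
            nh.kmeans_hub_clusters(table, k=5)

    def test_manova_significant_on_separated_blobs(self, rng):
        table = _blob_table(rng, [(0, 0, 0, 0), (5, 5, 5, 5), (0, 5, 0, 5)], 15)
        hc = nh.kmeans_hub_clusters(table, k=3, seed=2, n_boot=20)
        assert hc.manova_p < 1e-6
        assert 0 <= hc.pillai <= min(hc.k - 1, 4)
        assert (hc.pairwise_f["p_value"] < 1e-3).all()


class TestPillaiManova:
    def test_pillai_range(self, rng):
        x = rng.normal(size=(60, 4))
        labels = rng.integers(0, 3, size=60)
        pillai, p = nh._pillai_manova(x, labels)
        assert 0 <= pillai <= min(2, 4)
        assert 0 <= p <= 1

    def test_null_p_uniform_under_permutation(self, rng):
        # p-value of the Pillai F approximation is ~uniform on null data
        pvals = []
        for _ in range(500):
            x = rng.normal(size=(30, 2))
            labels = np.repeat([0, 1, 2], 10)
            pvals.append(nh._pillai_manova(x, labels)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_matches_statsmodels_manova(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        x = rng.normal(size=(40, 3))
        labels = rng.integers(0, 3, size=40)
        x[labels == 2] += 1.0
        pillai, p = nh._pillai_manova(x, labels)
        df = pd.DataFrame(x, columns=["f1", "f2", "f3"])
        df["g"] = labels.astype(str)
        res = MANOVA.from_formula("f1 + f2 + f3 ~ g", data=df).mv_test()
        table = res.results["g"]["stat"]
        assert pillai == pytest.approx(float(table.loc["Pillai's trace", "Value"]), rel=1e-6)
        assert p == pytest.approx(float(table.loc["Pillai's trace", "Pr > F"]), rel=1e-4)


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------


class TestHypergeomEnrichment:
    def test_degenerate_full_overlap(self):
        bg = {f"g{i}" for i in range(10)}
        db = PathwayDB(sets={"P1": set(bg)})
        res = nh.hypergeom_enrichment(set(bg), db, bg, min_genes=1)
        assert res.iloc[0]["n_genes_in_set"] == 10
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_disjoint_overlap_zero(self):
        bg = {f"g{i}" for i in range(20)}
        db = PathwayDB(sets={"P1": {"g0", "g1"}})
        res = nh.hypergeom_enrichment({"g10", "g11"}, db, bg, min_genes=0)
        assert res.iloc[0]["n_genes_in_set"] == 0
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_tail_matches_pmf_enumeration(self):
        # oracle: exhaustive sum of hypergeometric pmf over the upper tail
        bg = {f"g{i}" for i in range(15)}
        members = {f"g{i}" for i in range(6)}
        draw = {"g0", "g1", "g2", "g7", "g8"}
        db = PathwayDB(sets={"P1": members})
        res = nh.hypergeom_enrichment(draw, db, bg, min_genes=0)
        k = len(draw & members)
        expected = sum(stats.hypergeom.pmf(i, 15, 6, 5) for i in range(k, 6))
        assert res.iloc[0]["p_value"] == pytest.approx(expected)

    def test_non_subset_errors(self):
        db = PathwayDB(sets={"P1": {"a"}})
        with pytest.raises(ValueError, match="subset"):
            nh.hypergeom_enrichment({"zzz"}, db, {"a", "b"})

    def test_empty_background_errors(self):
        db = PathwayDB(sets={"P1": {"a"}})
        with pytest.raises(ValueError, match="background"):
            nh.hypergeom_enrichment(set(), db, set())


# ---------------------------------------------------------------------------
# ward_signal_clusters
# ---------------------------------------------------------------------------


class TestWardSignalClusters:
    def test_planted_blocks_recovered(self, rng):
        # three correlation blocks across individuals -> exact recovery
        n_ind = 12
        factors = rng.normal(size=(3, n_ind))
        rows, names = [], []
        for b in range(3):
            for j in range(5):
                rows.append(factors[b] + rng.normal(0, 0.1, n_ind))
                names.append(f"b{b}_g{j}")
        df = pd.DataFrame(rows, index=names)
        labels, support = nh.ward_signal_clusters(df, n_clusters=3, n_boot=30, seed=0)
        for b in range(3):
            block = labels[[f"b{b}_g{j}" for j in range(5)]]
            assert block.nunique() == 1
        assert labels.nunique() == 3

    def test_dissimilarity_extremes(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert 1 - np.corrcoef(x, 2 * x + 1)[0, 1] == pytest.approx(0.0)
        assert 1 - np.corrcoef(x, -x)[0, 1] == pytest.approx(2.0)

    def test_constant_row_dropped_with_warning(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 6)), index=[f"g{i}" for i in range(5)])
        df.loc["g0"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            labels, _ = nh.ward_signal_clusters(df, n_clusters=2, n_boot=5, seed=0)
        assert "g0" not in labels.index

    def test_too_small_errors(self, rng):
        df = pd.DataFrame(rng.normal(size=(2, 5)))
        with pytest.raises(ValueError, match=">= 3 genes"):
            nh.ward_signal_clusters(df, n_clusters=2)


# ---------------------------------------------------------------------------
# map_clusters_to_network
# ---------------------------------------------------------------------------


class TestMapClusters:
    def _clique_plus_isolates(self):
        pairs = [(f"c{a}", f"c{b}") for a, b in itertools.combinations(range(5), 2)]
        pairs += [("i0", "x0"), ("i1", "x1"), ("i2", "x2")]  # low-degree periphery
        return _edges(pairs)

    def test_clique_fraction_one(self):
        t = self._clique_plus_isolates()
        maps = nh.map_clusters_to_network({"clq": {f"c{i}" for i in range(5)}}, t,
                                          score_threshold=0.5, min_degree=3,
                                          n_random=50, seed=0)
        assert maps[0].fraction == pytest.approx(1.0)

    def test_isolated_nodes_fraction_zero(self):
        t = self._clique_plus_isolates()
        maps = nh.map_clusters_to_network({"iso": {"i0", "i1", "i2"}}, t,
                                          score_threshold=0.5, min_degree=3,
                                          n_random=50, seed=0)
        assert maps[0].fraction == 0.0

    def test_planted_hub_cluster_significant(self, rng):
        # dense planted module inside a sparse random graph
        base = nx.gnp_random_graph(60, 0.03, seed=1)
        graph = nx.relabel_nodes(base, {i: f"n{i}" for i in base.nodes})
        module = [f"n{i}" for i in range(8)]
        for a, b in itertools.combinations(module, 2):
            graph.add_edge(a, b)
        t = _edges(list(graph.edges))
        maps = nh.map_clusters_to_network({"mod": set(module)}, t,
                                          score_threshold=0.5, min_degree=3,
                                          n_random=300, seed=0)
        assert maps[0].empirical_p < 0.05

    def test_relabeling_invariance(self, rng):
        base = nx.gnp_random_graph(25, 0.15, seed=3)
        t1 = _edges([(f"n{a}", f"n{b}") for a, b in base.edges])
        perm = rng.permutation(25)
        relab = {i: f"m{perm[i]}" for i in range(25)}
        t2 = _edges([(relab[a], relab[b]) for a, b in base.edges])
        cluster1 = {f"n{i}" for i in range(8)}
        cluster2 = {relab[i] for i in range(8)}
        m1 = nh.map_clusters_to_network({"c": cluster1}, t1, 0.5, 2, n_random=10, seed=0)
        m2 = nh.map_clusters_to_network({"c": cluster2}, t2, 0.5, 2, n_random=10, seed=0)
        assert m1[0].fraction == pytest.approx(m2[0].fraction)

    def test_cluster_exceeding_universe_errors(self):
        t = _edges([("A", "B")])
        with pytest.raises(ValueError, match="universe"):
            nh.map_clusters_to_network({"c": {"A", "B", "C"}}, t, 0.0, 0, n_random=5)
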