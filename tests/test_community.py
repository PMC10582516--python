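import itertools

import igraph as ig
import numpy as np
import pytest

import bionetkit as bk
from bionetkit.community import ALGORITHMS, clustering_summary

from conftest import clique_pair, int_edges, random_named_graph
from oracles import brute_modularity, max_modularity_partition


def labels_of(g, cl):
    return [cl.membership[v] for v in g.vs["name"]]


class TestCluster:
    @pytest.mark.parametrize("alg", ["fc", "wt", "louvain", "infomap", "spectral", "sg"])
    def test_two_cliques_split_cleanly(self, alg, two_cliques5):
        cl = bk.cluster(two_cliques5, alg, seed=7)
        assert cl.n_communities == 2
        groups = cl.communities()
        assert {frozenset(c) for c in groups} == {
            frozenset(f"a{i}" for i in range(5)),
            frozenset(f"b{i}" for i in range(5)),
        }

    def test_edgeless_graph_gives_singletons(self):
        g = ig.Graph(3)
        g.vs["name"] = ["x", "y", "z"]
        cl = bk.cluster(g, "fc")
        assert cl.n_communities == 3 and cl.modularity == 0.0

    def test_unknown_algorithm_rejected(self, two_cliques5):
        with pytest.raises(ValueError, match="unknown algorithm"):
            bk.cluster(two_cliques5, "magic")

    @pytest.mark.parametrize("alg", ALGORITHMS)
    def test_stored_q_matches_recomputation(self, alg, two_cliques5):
        cl = bk.cluster(two_cliques5, alg, seed=3)
        assert cl.modularity == pytest.approx(
            bk.modularity(two_cliques5, cl.membership), abs=1e-9
        )

    def test_membership_consecutive_one_based(self):
        g = random_named_graph(20, 0.2, 5)
        cl = bk.cluster(g, "louvain", seed=1)
        seen = sorted(set(cl.membership.values()))
        assert seen == list(range(1, len(seen) + 1))

    def test_deterministic_algorithms_permutation_equivariant(self):
        g = random_named_graph(15, 0.25, 8)
        cl1 = bk.cluster(g, "fc")
        perm = np.random.default_rng(0).permutation(g.vcount()).tolist()
        cl2 = bk.cluster(g.permute_vertices(perm), "fc")
        assert cl1.membership == cl2.membership


class TestModularity:
    def test_single_community_zero(self, two_cliques5):
        q = bk.modularity(two_cliques5, {v: 1 for v in two_cliques5.vs["name"]})
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_cliques_half(self):
        g = bk.build_network(
            [(f"a{i}", f"a{j}") for i, j in itertools.combinations(range(4), 2)]
            + [(f"b{i}", f"b{j}") for i, j in itertools.combinations(range(4), 2)]
        )
        member = {v: (1 if v.startswith("a") else 2) for v in g.vs["name"]}
        assert bk.modularity(g, member) == pytest.approx(0.5)

    def test_matches_double_sum_formula(self):
        rng = np.random.default_rng(2)
        for seed in range(10):
            g = random_named_graph(9, 0.3, seed)
            if g.ecount() == 0:
                continue
            labels = rng.integers(0, 3, g.vcount()).tolist()
            member = dict(zip(g.vs["name"], labels))
            assert bk.modularity(g, member) == pytest.approx(
                brute_modularity(g.vcount(), int_edges(g), labels), abs=1e-12
            )

    def test_matches_igraph(self):
        for seed in range(5):
            g = random_named_graph(12, 0.25, seed)
            if g.ecount() == 0:
                continue
            labels = np.random.default_rng(seed).integers(0, 4, g.vcount()).tolist()
            assert bk.modularity(g, dict(zip(g.vs["name"], labels))) == pytest.approx(
                g.modularity(labels), abs=1e-12
            )

    def test_no_edges_rejected(self):
        g = ig.Graph(2)
        g.vs["name"] = ["a", "b"]
        with pytest.raises(ValueError):
            bk.modularity(g, {"a": 1, "b": 1})


class TestSpectral:
    def test_single_clique_indivisible(self):
        g = bk.build_network([(f"v{i}", f"v{j}") for i, j in itertools.combinations(range(5), 2)])
        cl = bk.spectral_cluster(g)
        assert cl.n_communities == 1 and cl.modularity == pytest.approx(0.0, abs=1e-12)

    def test_two_small_cliques_exact_split(self):
        g = clique_pair(4)
        cl = bk.spectral_cluster(g)
        _, best = max_modularity_partition(g.vcount(), int_edges(g))
        best_sets = {frozenset(g.vs[b]["name"] for b in block) for block in best}
        assert {frozenset(c) for c in cl.communities()} == best_sets

    def test_near_optimal_on_exhaustive_oracle(self):
        """Spectral and fast-greedy land within 0.05 of the exhaustive optimum Q."""
        for seed in range(8):
            g = random_named_graph(8, 0.3, seed)
            if g.ecount() < 2:
                continue
            q_best, _ = max_modularity_partition(g.vcount(), int_edges(g))
            assert bk.spectral_cluster(g).modularity >= q_best - 0.05
            assert bk.cluster(g, "fc").modularity >= q_best - 0.05

    def test_fine_tuning_never_hurts(self):
        for seed in range(30):
            g = random_named_graph(np.random.default_rng(seed).integers(8, 20), 0.25, seed)
            if g.ecount() == 0:
                continue
            q_ft = bk.spectral_cluster(g, fine_tune=True).modularity
            q_plain = bk.spectral_cluster(g, fine_tune=False).modularity
            assert q_ft >= q_plain - 1e-9

    def test_planted_partition_recovery(self):
        from sklearn.metrics import normalized_mutual_info_score as nmi

        pg = bk.planted_partition(4, 16, 0.5, 0.02, seed=0)
        cl = bk.spectral_cluster(pg.graph)
        names = pg.graph.vs["name"]
        truth = [pg.true_membership[v] for v in names]
        assert nmi(truth, labels_of(pg.graph, cl)) == pytest.approx(1.0)


class TestNormalizedModularity:
    def test_deterministic_given_seed(self, two_cliques5):
        cl = bk.cluster(two_cliques5, "fc")
        a = bk.normalized_modularity(two_cliques5, cl, n_rand=10, seed=5)
        b = bk.normalized_modularity(two_cliques5, cl, n_rand=10, seed=5)
        assert a.q_norm == b.q_norm

    def test_planted_structure_above_null(self):
        pg = bk.planted_partition(4, 12, 0.8, 0.02, seed=1)
        cl = bk.cluster(pg.graph, "fc")
        res = bk.normalized_modularity(pg.graph, cl, n_rand=10, seed=2)
        assert res.q_norm > 1.0

    def test_random_graph_near_null(self):
        g = bk.random_graph("gnp", {"n": 60, "p": 0.15}, seed=3)
        g = bk.largest_connected_component(g)
        cl = bk.cluster(g, "fc")
        res = bk.normalized_modularity(g, cl, n_rand=10, seed=4)
        assert abs(res.q_obs - res.null_mean) <= 2 * res.null_sd

    def test_too_few_replicates_rejected(self, two_cliques5):
        with pytest.raises(ValueError):
            bk.normalized_modularity(two_cliques5, bk.cluster(two_cliques5, "fc"), n_rand=5)


class TestRecluster:
    def test_threshold_above_max_size_is_noop(self, two_cliques5):
        cl = bk.cluster(two_cliques5, "fc")
        out = bk.recluster(two_cliques5, cl, size_threshold=50)
        assert out.membership == cl.membership

    def test_merged_cliques_get_split(self):
        g = clique_pair(4)
        merged = bk.Clustering(
            algorithm="fc", membership={v: 1 for v in g.vs["name"]}, modularity=0.0
        )
        out = bk.recluster(g, merged, size_threshold=6, algorithm="fc")
        assert out.n_communities == 2

    def test_output_is_valid_partition(self):
        g = random_named_graph(25, 0.15, 9)
        cl = bk.cluster(g, "louvain", seed=0)
        out = bk.recluster(g, cl, size_threshold=4, algorithm="fc", recurse=True)
        assert set(out.membership) == set(g.vs["name"])
        seen = sorted(set(out.membership.values()))
        assert seen == list(range(1, len(seen) + 1))


class TestClusteringSummary:
    def test_disjoint_cliques_mu_zero(self):
        g = bk.build_network(
            [(f"a{i}", f"a{j}") for i, j in itertools.combinations(range(4), 2)]
            + [(f"b{i}", f"b{j}") for i, j in itertools.combinations(range(4), 2)]
        )
        cl = bk.cluster(g, "fc")
        row = clustering_summary(g, [cl]).loc["fc"]
        assert row["mu"] == 0.0 and row["C"] == 2

    def test_edgeless_singletons_counted(self):
        g = ig.Graph(3)
        g.vs["name"] = ["x", "y", "z"]
        cl = bk.cluster(g, "fc")
        row = clustering_summary(g, [cl]).loc["fc"]
        assert row["C"] == 3 and row["Cn1"] == 3

    def test_quartile_columns_ordered(self):
        g = random_named_graph(30, 0.15, 4)
        cls = [bk.cluster(g, a, seed=1) for a in ("fc", "louvain")]
        df = clustering_summary(g, cls)
        for _, row in df.iterrows():
            q = row[["Min. C", "1st Qu. C", "Median C", "3rd Qu. C", "Max. C"]].to_numpy()
            assert (np.diff(q.astype(float)) >= 0).all()
            assert row["C"] >= row["Cn1"] + row["Cn100"]


class TestClusterLayout:
    def test_single_community_layout(self, two_cliques5):
        member = {v: 1 for v in two_cliques5.vs["name"]}
        df = bk.cluster_layout(two_cliques5, member, seed=0)
        assert len(df) == two_cliques5.vcount()

    def test_community_bounding_boxes_disjoint(self):
        pg = bk.planted_partition(4, 10, 0.8, 0.0, seed=0)
        cl = bk.cluster(pg.graph, "fc")
        df = bk.cluster_layout(pg.graph, cl, seed=1)
        df["comm"] = [cl.membership[v] for v in df["vertex_id"]]
        boxes = {
            c: (sub["x"].min(), sub["x"].max(), sub["y"].min(), sub["y"].max())
            for c, sub in df.groupby("comm")
        }
        for c1, c2 in itertools.combinations(boxes, 2):
            x0, x1, y0, y1 = boxes[c1]
            u0, u1, v0, v1 = boxes[c2]
            assert x1 < u0 or u1 < x0 or y1 < v0 or v1 < y0

    def test_large_graph_completes(self):
        pg = bk.planted_partition(40, 50, 0.15, 0.001, seed=2)
        cl = bk.cluster(pg.graph, "louvain", seed=0)
        df = bk.cluster_layout(pg.graph, cl, seed=0)
        assert len(df) == 2000 and df[["x", "y"]].notna().all().all()

    def test_deterministic_given_seed(self, two_cliques5):
        cl = bk.cluster(two_cliques5, "fc")
        a = bk.cluster_layout(two_cliques5, cl, seed=3)
        b = bk.cluster_layout(two_cliques5, cl, seed=3)
        assert a.equals(b)
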