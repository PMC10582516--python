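import numpy as np
import pandas as pd
import pytest

import bionetkit as bk
from bionetkit.annot_stats import annotation_sets

from conftest import int_edges, random_named_graph
from oracles import bfs_distances, hypergeom_tail_exact


def annotate_random(g, n_terms, term_size, seed):
    rng = np.random.default_rng(seed)
    rows = []
    names = g.vs["name"]
    for t in range(n_terms):
        for v in rng.choice(len(names), size=term_size, replace=False):
            rows.append({"term_id": f"T{t:02d}", "term_name": f"term {t}",
                         "vertex_id": names[int(v)]})
    bk.annotate_vertices(g, pd.DataFrame(rows), "ann")
    return g


class TestMeanSetDistance:
    def test_path_endpoints_within(self, path5):
        assert bk.mean_set_distance(path5, ["v1", "v5"], None, mode="within") == 4.0

    def test_identical_sets_between_zero(self, path5):
        assert bk.mean_set_distance(path5, ["v1", "v3"], ["v1", "v3"], mode="between") == 0.0

    def test_disconnected_sets_rejected(self, triangle_plus_edge):
        with pytest.raises(ValueError, match="no finite distances"):
            bk.mean_set_distance(triangle_plus_edge, ["A", "B"], ["D", "E"], mode="between")

    def test_within_needs_two_members(self, path5):
        with pytest.raises(ValueError):
            bk.mean_set_distance(path5, ["v1"], None, mode="within")


class TestSeparation:
    def test_self_pair_is_nonpositive(self, path5):
        res = bk.separation(path5, ["v1", "v3"], ["v1", "v3"])
        assert res.s_ab == pytest.approx(-res.d_aa) and res.s_ab <= 0

    def test_matches_bruteforce_distance_matrices(self):
        """s_AB agrees with direct evaluation on hand-rolled BFS distances."""
        rng = np.random.default_rng(1)
        for seed in range(8):
            g = bk.largest_connected_component(random_named_graph(14, 0.2, seed))
            if g.vcount() < 6:
                continue
            names = g.vs["name"]
            A = rng.choice(len(names), size=3, replace=False)
            B = rng.choice(len(names), size=3, replace=False)
            res = bk.separation(g, [names[i] for i in A], [names[i] for i in B])
            D = bfs_distances(g.vcount(), int_edges(g))
            d = lambda rows, cols, excl: [
                min(D[r, c] for c in cols if not (excl and c == r)) for r in rows
                if any(not (excl and c == r) for c in cols)
            ]
            d_aa = np.mean(d(A, A, True))
            d_bb = np.mean(d(B, B, True))
            d_ab = np.mean(d(A, B, False) + d(B, A, False))
            assert res.s_ab == pytest.approx(d_ab - (d_aa + d_bb) / 2, abs=1e-12)

    def test_planted_blocks_separate_and_cohere(self):
        hits_sep, hits_ovl = 0, 0
        n_seeds = 12
        for seed in range(n_seeds):
            pg = bk.planted_partition(2, 20, 0.5, 0.02, seed=seed)
            rng = np.random.default_rng(100 + seed)
            names = pg.graph.vs["name"]
            block1 = [v for v in names if pg.true_membership[v] == 1]
            block2 = [v for v in names if pg.true_membership[v] == 2]
            a = rng.choice(block1, 6, replace=False)
            b = rng.choice(block2, 6, replace=False)
            c = rng.choice(block1, 6, replace=False)
            if bk.separation(pg.graph, a, b).s_ab > 0:
                hits_sep += 1
            if bk.separation(pg.graph, a, c).s_ab < 0:
                hits_ovl += 1
        assert hits_sep >= 0.9 * n_seeds
        assert hits_ovl >= 0.9 * n_seeds


class TestAnnotationPairs:
    def test_permutation_preserves_term_counts(self):
        g = annotate_random(random_named_graph(25, 0.2, 0), 4, 5, seed=0)
        sets = annotation_sets(g, "ann")
        out = bk.calc_annotation_pairs(g, "ann", seed=1)
        assert all(len(sets[t]) == 5 for t in sets)
        assert len(out) == 6  # C(4,2) pairs

    def test_seeded_reproducibility(self):
        g = annotate_random(random_named_graph(25, 0.2, 0), 4, 5, seed=0)
        a = bk.calc_annotation_pairs(g, "ann", seed=3)
        b = bk.calc_annotation_pairs(g, "ann", seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_overlap_below_permuted(self):
        """A pair planted in one block scores lower s_AB than its permuted twin."""
        pg = bk.planted_partition(3, 12, 0.55, 0.03, seed=42)
        ann = bk.annotated_planted_graph(pg, 4, 8, overlap_mode="same_block", seed=42)
        bk.annotate_vertices(pg.graph, ann, "ann")
        out = bk.calc_annotation_pairs(pg.graph, "ann", pairs=[("T000", "T001")], seed=0)
        assert out.loc[0, "s_obs"] < out.loc[0, "s_permuted"]

    def test_absent_term_named_in_error(self):
        g = annotate_random(random_named_graph(20, 0.25, 0), 3, 5, seed=0)
        with pytest.raises(ValueError, match="T99"):
            bk.calc_annotation_pairs(g, "ann", pairs=[("T00", "T99")])


class TestPermutationTest:
    def test_bonferroni_column(self):
        g = annotate_random(random_named_graph(30, 0.2, 2), 4, 6, seed=2)
        out = bk.run_permutation_test(g, "ann", n_perm=100, seed=0)
        np.testing.assert_allclose(
            out["p_bonferroni"], np.minimum(1.0, out["p"] * len(out))
        )
        assert ((out["p"] > 0) & (out["p"] <= 1)).all()

    def test_planted_overlap_ranks_first_by_q(self):
        """A strongly overlapping planted pair beats random pairs in every seed."""
        for seed in range(5):
            pg = bk.planted_partition(4, 14, 0.6, 0.03, seed=seed)
            ann = bk.annotated_planted_graph(pg, 6, 8, overlap_mode="same_block",
                                            seed=seed)
            g = bk.largest_connected_component(pg.graph)
            bk.annotate_vertices(g, ann, "ann")
            out = bk.run_permutation_test(
                g, "ann", pairs=[("T000", "T001"), ("T000", "T003"), ("T002", "T005")],
                n_perm=200, seed=seed,
            )
            ranked = out.sort_values("q", kind="stable").iloc[0]
            assert {ranked["term_a"], ranked["term_b"]} == {"T000", "T001"}

    def test_q_monotone_in_p(self):
        g = annotate_random(random_named_graph(30, 0.2, 5), 5, 6, seed=4)
        out = bk.run_permutation_test(g, "ann", n_perm=100, seed=1).sort_values("p")
        assert (out["q"].diff().dropna() >= -1e-12).all()


class TestORA:
    def test_exact_small_case(self):
        ann = pd.DataFrame({"term_id": ["T1"] * 5, "term_name": ["t"] * 5,
                            "vertex_id": [f"v{i}" for i in range(5)]})
        out = bk.ora({"g": {f"v{i}" for i in range(4)}}, ann,
                     {f"v{i}" for i in range(10)})
        assert out.loc[0, "p"] == pytest.approx(5 / 210)
        assert out.loc[0, "vertices"] == "v0;v1;v2;v3"

    def test_zero_overlap_rows_omitted_by_default(self):
        ann = pd.DataFrame({"term_id": ["T1"], "term_name": ["t"], "vertex_id": ["v9"]})
        universe = {f"v{i}" for i in range(10)}
        assert len(bk.ora({"g": {"v0", "v1"}}, ann, universe)) == 0
        out = bk.ora({"g": {"v0", "v1"}}, ann, universe, include_zero=True)
        assert out.loc[0, "p"] == 1.0

    def test_group_equal_to_term_is_most_significant(self):
        rows = []
        for t, size in [("T1", 4), ("T2", 8)]:
            rows += [{"term_id": t, "term_name": t, "vertex_id": f"v{i}"}
                     for i in range(size)]
        out = bk.ora({"g": {f"v{i}" for i in range(4)}}, pd.DataFrame(rows),
                     {f"v{i}" for i in range(20)})
        best = out.sort_values("p").iloc[0]
        assert best["term_id"] == "T1"

    def test_matches_exact_combinatorics(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"v{i}" for i in range(N)]
            ann = pd.DataFrame({"term_id": ["T"] * K, "term_name": ["t"] * K,
                                "vertex_id": universe[:K]})
            group = set(rng.choice(universe, size=n, replace=False).tolist())
            out = bk.ora({"g": group}, ann, set(universe))
            k = len(group & set(universe[:K]))
            if k == 0:
                assert len(out) == 0
                continue
            assert out.loc[0, "p"] == pytest.approx(
                float(hypergeom_tail_exact(k, N, K, n)), rel=1e-10
            )

    def test_empty_universe_rejected(self):
        ann = pd.DataFrame({"term_id": ["T"], "term_name": ["t"], "vertex_id": ["v"]})
        with pytest.raises(ValueError, match="universe"):
            bk.ora({"g": {"v"}}, ann, set())


class TestIntraClassEdges:
    def test_single_class_counts_all_edges(self, two_cliques5):
        two_cliques5.vs["klass"] = ["same"] * two_cliques5.vcount()
        res = bk.intra_class_edges(two_cliques5, "klass", n_perm=100, seed=0)
        assert res.observed == two_cliques5.ecount() and res.p == 1.0

    def test_assortative_classes_significant(self):
        for seed in range(5):
            pg = bk.planted_partition(3, 12, 0.5, 0.02, seed=seed)
            pg.graph.vs["klass"] = [str(pg.true_membership[v]) for v in pg.graph.vs["name"]]
            res = bk.intra_class_edges(pg.graph, "klass", n_perm=300, seed=seed)
            assert res.p <= 0.01

    def test_null_mean_matches_analytic_expectation(self):
        g = random_named_graph(40, 0.15, 3)
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, g.vcount())
        g.vs["klass"] = [str(c) for c in labels]
        res = bk.intra_class_edges(g, "klass", n_perm=500, seed=2)
        n = g.vcount()
        sizes = np.bincount(labels)
        expected = (sizes * (sizes - 1)).sum() / (n * (n - 1)) * g.ecount()
        assert abs(res.null_mean - expected) <= 3 * res.null_sd
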