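import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mircade.scoring import (
    GeneScore,
    ScoredPath,
    combined_gene_score,
    compute_edge_scores,
    extract_top_subnetwork,
    score_paths,
)
from mircade.targets import DirectTargetCall


def build_graph(a_edges, b_edges, c_edges):
    g = nx.DiGraph()
    for (m, t), s in a_edges.items():
        g.add_node(m, node_type="mirna")
        g.add_node(t, node_type="tf")
        g.add_edge(m, t, layer="a", score=s)
    for (t, r), s in b_edges.items():
        g.add_node(t, node_type="tf")
        g.add_node(r, node_type="region")
        g.add_edge(t, r, layer="b", score=s)
    for (r, gg), s in c_edges.items():
        g.add_node(r, node_type="region")
        g.add_node(gg, node_type="gene")
        g.add_edge(r, gg, layer="c", score=s)
    return g


def dfs_oracle(g):
    """Brute-force path enumeration by explicit depth-first recursion,
    independent of score_paths' edge iteration."""
    paths = []

    def walk(node, trail, total):
        data = g.nodes[node]
        if data["node_type"] == "gene":
            paths.append((tuple(trail), total))
            return
        for _, nxt, d in g.edges(node, data=True):
            walk(nxt, trail + [nxt], total + d["score"])

    for n, d in g.nodes(data=True):
        if d["node_type"] == "mirna":
            walk(n, [n], 0.0)
    return paths


class TestComputeEdgeScores:
    def _setup(self, site_type, evidence, p_value):
        g = nx.DiGraph()
        g.add_node("m1", node_type="mirna")
        g.add_node("tf1", node_type="tf")
        g.add_node("r1", node_type="region")
        g.add_node("g1", node_type="gene")
        g.add_edge("m1", "tf1", layer="a")
        g.add_edge("tf1", "r1", layer="b", motif_score=8.0)
        g.add_edge("r1", "g1", layer="c")
        calls = [DirectTargetCall("tf1", {"m1"}, evidence,
                                  site_types={"m1": site_type} if site_type else {})]
        hits = pd.DataFrame({"peak_id": ["r1"], "tf_id": ["tf1"],
                             "score": [8.0], "strand": ["+"]})
        de = pd.DataFrame({"p_value": [p_value]}, index=["g1"])
        return compute_edge_scores(g, calls, hits, de)

    def test_8mer_with_clip_gives_full_a_score(self):
        g = self._setup("8mer", "seed_and_clip", 1e-4)
        assert g.edges["m1", "tf1"]["score"] == pytest.approx(1.0)

    def test_7mer_a1_without_clip(self):
        g = self._setup("7mer-A1", "seed_only", 1e-4)
        assert g.edges["m1", "tf1"]["score"] == pytest.approx(0.5 / 3)

    @pytest.mark.parametrize("p,expected", [(1e-4, 1.0), (1e-2, 0.5)])
    def test_c_score_from_p_value(self, p, expected):
        g = self._setup("8mer", "seed_only", p)
        assert g.edges["r1", "g1"]["score"] == pytest.approx(expected)

    def test_single_hit_pwm_normalizes_to_one(self):
        g = self._setup("8mer", "seed_only", 1e-4)
        assert g.edges["tf1", "r1"]["score"] == pytest.approx(1.0)

    def test_missing_evidence_errors(self):
        g = nx.DiGraph()
        g.add_node("m1", node_type="mirna")
        g.add_node("tf1", node_type="tf")
        g.add_edge("m1", "tf1", layer="a")
        with pytest.raises(ValueError, match="no direct-target evidence"):
            compute_edge_scores(g, [], pd.DataFrame(columns=["peak_id", "tf_id", "score"]),
                                pd.DataFrame(columns=["p_value"]))


class TestScorePaths:
    def test_sum_of_edge_scores(self):
        g = build_graph({("m", "t"): 0.5}, {("t", "r"): 0.3}, {("r", "g"): 0.2})
        paths = score_paths(g)
        assert len(paths) == 1
        assert paths[0].s == pytest.approx(1.0)

    def test_zero_edges_zero_path(self):
        g = build_graph({("m", "t"): 0.0}, {("t", "r"): 0.0}, {("r", "g"): 0.0})
        assert score_paths(g)[0].s == 0.0

    def test_exact_additivity(self):
        rng = np.random.default_rng(0)
        g = build_graph(
            {("m", f"t{i}"): rng.uniform() for i in range(4)},
            {(f"t{i}", f"r{i}{j}"): rng.uniform() for i in range(4) for j in range(3)},
            {(f"r{i}{j}", f"g{j}"): rng.uniform() for i in range(4) for j in range(3)},
        )
        for p in score_paths(g):
            assert p.s - (p.a + p.b + p.c) == 0.0

    def test_matches_dfs_oracle_on_random_layered_graphs(self):
        rng = np.random.default_rng(1)
        for trial in range(10):
            a = {(f"m{i}", f"t{j}"): float(rng.uniform())
                 for i in range(3) for j in range(4) if rng.random() < 0.6}
            b = {(f"t{j}", f"r{k}"): float(rng.uniform())
                 for j in range(4) for k in range(6) if rng.random() < 0.5}
            c = {(f"r{k}", f"g{k % 5}"): float(rng.uniform()) for k in range(6)}
            g = build_graph(a, b, c)
            got = {((p.mirna_id, p.tf_id, p.region_id, p.gene_id), round(p.s, 9))
                   for p in score_paths(g)}
            want = {((t[0], t[1], t[2], t[3]), round(s, 9))
                    for t, s in dfs_oracle(g)}
            assert got == want


def mk_path(m, g, s, tf="t", r="r"):
    return ScoredPath(m, tf, r, g, s, 0.0, 0.0, s)


class TestCombinedGeneScore:
    def test_sum_of_per_mirna_maxima(self):
        paths = [mk_path("m1", "gA", 2.0), mk_path("m1", "gA", 1.0, tf="t2"),
                 mk_path("m2", "gA", 1.5)]
        scores = combined_gene_score(paths)
        assert scores[0].combined == pytest.approx(3.5)
        assert scores[0].contributing_mirnas == {"m1", "m2"}

    def test_multi_mirna_gene_outranks_stronger_single_path(self):
        paths = [mk_path("m1", "gA", 3.0),
                 mk_path("m1", "gB", 2.0), mk_path("m2", "gB", 2.0)]
        scores = combined_gene_score(paths)
        assert [s.gene_id for s in scores] == ["gB", "gA"]
        assert scores[0].combined == pytest.approx(4.0)

    def test_single_mirna_gene(self):
        scores = combined_gene_score([mk_path("m1", "gA", 1.2)])
        assert scores[0].combined == pytest.approx(1.2)

    def test_adding_new_mirna_path_never_decreases(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            paths = [mk_path(f"m{i}", "g", float(rng.uniform(0, 3)))
                     for i in range(rng.integers(1, 5))]
            before = combined_gene_score(paths)[0].combined
            after = combined_gene_score(
                paths + [mk_path("m_new", "g", float(rng.uniform(0, 3)))]
            )[0].combined
            assert after >= before

    def test_increasing_edge_score_never_decreases_combined(self):
        base = build_graph({("m", "t"): 0.4}, {("t", "r"): 0.4}, {("r", "g"): 0.4})
        up = build_graph({("m", "t"): 0.9}, {("t", "r"): 0.4}, {("r", "g"): 0.4})
        s0 = combined_gene_score(score_paths(base))[0].combined
        s1 = combined_gene_score(score_paths(up))[0].combined
        assert s1 >= s0


class TestExtractTopSubnetwork:
    def _scores(self, n):
        return [GeneScore(f"g{i:03d}", float(n - i), {"m1"},
                          {"m1": mk_path("m1", f"g{i:03d}", float(n - i))})
                for i in range(n)]

    def test_restricted_top_k(self):
        scores = self._scores(100)
        restrict = {f"g{i:03d}" for i in range(0, 100, 2)}  # 50 genes (even)
        ranked, sub = extract_top_subnetwork(scores, restrict, k=40)
        assert len(ranked) == 40
        assert (ranked["combined"].diff().dropna() <= 0).all()
        assert set(ranked["gene_id"]) <= restrict

    def test_pool_smaller_than_k(self):
        scores = self._scores(25)
        ranked, _ = extract_top_subnetwork(scores, {s.gene_id for s in scores}, k=40)
        assert len(ranked) == 25

    def test_equal_scores_lexicographic(self):
        scores = [
            GeneScore(g, 2.0, {"m1"}, {"m1": mk_path("m1", g, 2.0)})
            for g in ["gB", "gA", "gC"]
        ]
        ranked, _ = extract_top_subnetwork(scores, None, k=3)
        assert list(ranked["gene_id"]) == ["gA", "gB", "gC"]

    def test_disjoint_restriction_returns_empty(self):
        ranked, sub = extract_top_subnetwork(self._scores(5), {"zzz"}, k=3)
        assert ranked.empty
        assert sub.number_of_nodes() == 0

    def test_subgraph_contains_best_paths_nodes(self):
        scores = self._scores(5)
        ranked, sub = extract_top_subnetwork(scores, None, k=2)
        assert {"m1", "t", "r"} <= set(sub.nodes)
        assert sub.nodes["m1"]["node_type"] == "mirna"
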