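import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mircade.chromatin import (
    GenomicInterval,
    assemble_graph,
    assign_peaks_to_tss,
    classify_histone_dynamics,
    dinucleotide_shuffle,
    dynamic_peaks,
    mann_whitney,
    scan_motifs,
    tss_position,
    validate_histone_expression_link,
)


def iv(chrom, start, end, name=".", score=None, strand=None):
    return GenomicInterval(chrom, start, end, name, score, strand)


class TestAssignPeaksToTss:
    TSS = [iv("chr1", 100_000, 100_001, "gA", strand="+")]

    def test_within_window_assigned_by_midpoint(self):
        out = assign_peaks_to_tss([iv("chr1", 94_000, 95_000, "p1")], self.TSS)
        assert out.iloc[0].tolist() == ["p1", "gA", 5500.0]

    def test_beyond_window_unassigned(self):
        out = assign_peaks_to_tss([iv("chr1", 110_500, 111_500, "p1")], self.TSS)
        assert out.empty

    def test_closest_of_two_tss_wins(self):
        tss = self.TSS + [iv("chr1", 103_000, 103_001, "gB", strand="+")]
        # midpoint 95,000: 5,000 from gA, 8,000 from gB
        out = assign_peaks_to_tss([iv("chr1", 94_500, 95_500, "p1")], tss)
        assert out.iloc[0]["gene_id"] == "gA"

    def test_distance_tie_broken_by_gene_id(self):
        tss = [iv("chr1", 90, 91, "gZ", strand="+"), iv("chr1", 110, 111, "gB", strand="+")]
        out = assign_peaks_to_tss([iv("chr1", 99, 102, "p1")], tss)  # midpoint 100.5
        assert out.iloc[0]["gene_id"] == "gB"

    def test_missing_chromosome_unassigned(self):
        out = assign_peaks_to_tss([iv("chr9", 10, 20, "p1")], self.TSS)
        assert out.empty

    def test_fdr_filter_applied(self):
        peaks = [iv("chr1", 99_000, 99_200, "p1", score=0.5),
                 iv("chr1", 99_000, 99_200, "p2", score=0.001)]
        out = assign_peaks_to_tss(peaks, self.TSS, peak_fdr_max=0.01)
        assert list(out["peak_id"]) == ["p2"]

    def test_strand_aware_tss_position(self):
        assert tss_position(iv("chr1", 10, 50, strand="+")) == 10
        assert tss_position(iv("chr1", 10, 50, strand="-")) == 49

    def test_matches_all_pairs_oracle_on_random_sets(self):
        rng = np.random.default_rng(5)
        tss = [iv("chr1", p, p + 1, f"g{i}", strand="+")
               for i, p in enumerate(sorted(rng.integers(0, 200_000, 30)))]
        peaks = [iv("chr1", s, s + 200, f"p{i}")
                 for i, s in enumerate(rng.integers(0, 200_000, 60))]
        out = assign_peaks_to_tss(peaks, tss, max_distance=10_000)
        got = {r["peak_id"]: (r["gene_id"], r["distance"]) for _, r in out.iterrows()}
        for p in peaks:
            dists = sorted(
                (abs(tss_position(t) - p.midpoint), t.name) for t in tss
            )
            d, g = dists[0]
            if d > 10_000:
                assert p.name not in got
            else:
                assert got[p.name] == (g, d)


class TestHistoneDynamics:
    def test_closed_form_classification(self):
        pe = pd.DataFrame({"H3K4me3": [8.0]}, index=["p1"])
        isl = pd.DataFrame({"H3K4me3": [2.0]}, index=["p1"])
        out = classify_histone_dynamics(pe, isl, threshold=1.0, pseudocount=1.0)
        assert out.loc[0, "log2fc_pe_over_islet"] == pytest.approx(np.log2(3))
        assert out.loc[0, "class"] == "up_in_pe"

    def test_equal_signal_is_stable(self):
        pe = pd.DataFrame({"H3K27ac": [5.0]}, index=["p1"])
        out = classify_histone_dynamics(pe, pe.copy())
        assert out.loc[0, "class"] == "stable"

    def test_missing_peak_errors(self):
        pe = pd.DataFrame({"H3K27ac": [5.0]}, index=["p1"])
        isl = pd.DataFrame({"H3K27ac": [5.0]}, index=["p2"])
        with pytest.raises(ValueError, match="missing"):
            classify_histone_dynamics(pe, isl)

    def test_dynamic_peak_gating_any_vs_all(self):
        dyn = pd.DataFrame({
            "peak_id": ["p1", "p1", "p2", "p2"],
            "mark": ["H3K4me3", "H3K27ac"] * 2,
            "log2fc_pe_over_islet": [2.0, 0.0, 2.0, 2.0],
            "class": ["up_in_pe", "stable", "up_in_pe", "up_in_pe"],
        })
        assert dynamic_peaks(dyn) == {"p1", "p2"}
        assert dynamic_peaks(dyn, require_both=True) == {"p2"}


class TestMannWhitney:
    def test_exact_one_in_twenty(self):
        """{4,5,6} stochastically greater than {1,2,3}: the most extreme of
        the C(6,3)=20 rank assignments, exact p = 1/20."""
        _, p = mann_whitney([4, 5, 6], [1, 2, 3], alternative="greater")
        assert p == pytest.approx(1 / 20)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (6, 8), (8, 8)])
    def test_matches_scipy_exact_without_ties(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.normal(0.5, 1, n1)
        y = rng.normal(0, 1, n2)
        u, p = mann_whitney(x, y, alternative="greater")
        ref = sps.mannwhitneyu(x, y, alternative="greater", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_tied_data_enumeration(self):
        # brute force over assignments of the pooled tied values
        x, y = np.array([2.0, 2.0, 3.0]), np.array([1.0, 2.0, 2.0])
        u_obs, p = mann_whitney(x, y, alternative="greater")
        pooled = np.concatenate([x, y])

        def u_of(idx):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            return sum((xi > ys).sum() + 0.5 * (xi == ys).sum() for xi in xs)

        combos = list(itertools.combinations(range(6), 3))
        expected = np.mean([u_of(c) >= u_obs for c in combos])
        assert p == pytest.approx(expected)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(300):
            x, y = rng.normal(size=5), rng.normal(size=5)
            ps.append(mann_whitney(x, y)[1])
        assert abs(np.mean(ps) - 0.5) < 0.07

    def test_large_sample_coupling_detected(self):
        rng = np.random.default_rng(2)
        up = rng.normal(1.0, 1.0, 50)
        down = rng.normal(0.0, 1.0, 50)
        _, p = mann_whitney(up, down, alternative="greater")
        assert p < 0.01


class TestValidateHistoneExpressionLink:
    def test_planted_coupling_detected(self):
        rng = np.random.default_rng(7)
        peaks = [f"p{i}" for i in range(100)]
        genes = [f"g{i}" for i in range(100)]
        classes = ["up_in_pe"] * 50 + ["down_in_pe"] * 50
        dyn = pd.DataFrame({
            "peak_id": peaks, "mark": "H3K27ac",
            "log2fc_pe_over_islet": [2.0] * 50 + [-2.0] * 50, "class": classes,
        })
        pg = pd.DataFrame({"peak_id": peaks, "gene_id": genes,
                           "distance": 100.0})
        fc = pd.Series(
            np.where(np.array(classes) == "up_in_pe",
                     rng.normal(1.0, 0.7, 100), rng.normal(0.0, 0.7, 100)),
            index=genes,
        )
        out = validate_histone_expression_link(dyn, pg, fc)
        assert out["p_up_greater"] < 0.01

    def test_empty_class_errors(self):
        dyn = pd.DataFrame({"peak_id": ["p1"], "mark": ["H3K27ac"],
                            "log2fc_pe_over_islet": [2.0], "class": ["up_in_pe"]})
        pg = pd.DataFrame({"peak_id": ["p1"], "gene_id": ["g1"], "distance": [0.0]})
        with pytest.raises(ValueError, match="down_in_pe"):
            validate_histone_expression_link(dyn, pg, pd.Series({"g1": 1.0}))


def _indicator_pwm(consensus: str, p: float = 0.97) -> np.ndarray:
    m = np.full((4, len(consensus)), (1 - p) / 3)
    for j, b in enumerate(consensus):
        m["ACGT".index(b), j] = p
    return m


class TestScanMotifs:
    def test_consensus_peak_hits_with_maximal_score(self):
        pwm = {"tf": _indicator_pwm("GATTACA")}
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        seqs = {f"p{i}": "".join(bases[rng.integers(4, size=80)]) for i in range(40)}
        seqs["hit"] = ("".join(bases[rng.integers(4, size=30)]) + "GATTACA"
                       + "".join(bases[rng.integers(4, size=30)]))
        hits = scan_motifs(pwm, seqs, seed=1)
        assert "hit" in set(hits["peak_id"])
        best = hits.set_index("peak_id").loc["hit", "score"]
        assert best == pytest.approx(7 * np.log2(0.97 / 0.25))

    def test_homopolymer_peak_scores_below_consensus(self):
        pwm = {"tf": _indicator_pwm("GATTACA")}
        seqs = {"c_only": "C" * 60, "real": "TTTT" + "GATTACA" + "TTTT"}
        hits = scan_motifs(pwm, seqs, seed=1)
        assert "c_only" not in set(hits["peak_id"])

    def test_reverse_complement_same_score_opposite_strand(self):
        from mircade.targets import reverse_complement

        pwm = {"tf": _indicator_pwm("GATTACA")}
        fwd = "ACCT" + "GATTACA" + "GGTA"
        seqs = {"f": fwd, "r": reverse_complement(fwd)}
        hits = scan_motifs(pwm, seqs, score_threshold_quantile=0.5, seed=2)
        h = hits.set_index("peak_id")
        assert h.loc["f", "score"] == pytest.approx(h.loc["r", "score"])
        assert {h.loc["f", "strand"], h.loc["r", "strand"]} == {"+", "-"}

    def test_bad_pwm_columns_error(self):
        bad = np.full((4, 5), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            scan_motifs({"tf": bad}, {"p": "ACGTACGT"}, seed=0)

    def test_dinucleotide_shuffle_preserves_doublets(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        for _ in range(10):
            s = "".join(bases[rng.integers(4, size=100)])
            t = dinucleotide_shuffle(s, rng)
            assert Counter(zip(s, s[1:])) == Counter(zip(t, t[1:]))
            assert t[0] == s[0] and t[-1] == s[-1]


class TestAssembleGraph:
    HITS = pd.DataFrame({"peak_id": ["r1"], "tf_id": ["tf1"],
                         "score": [8.0], "strand": ["+"]})
    PG = pd.DataFrame({"peak_id": ["r1"], "gene_id": ["g1"], "distance": [100.0]})

    def test_single_cascade_yields_one_path(self):
        g = assemble_graph({"m1": {"tf1"}}, self.HITS, self.PG, {"r1"}, {"g1"})
        assert set(g.nodes) == {"m1", "tf1", "r1", "g1"}
        assert [d["layer"] for _, _, d in g.edges(data=True)] == ["a", "b", "c"] or \
            sorted(d["layer"] for _, _, d in g.edges(data=True)) == ["a", "b", "c"]

    def test_peak_of_unregulated_gene_excluded(self):
        g = assemble_graph({"m1": {"tf1"}}, self.HITS, self.PG, {"r1"}, {"gX"})
        assert g.number_of_nodes() == 0

    def test_nondynamic_peak_excluded(self):
        g = assemble_graph({"m1": {"tf1"}}, self.HITS, self.PG, set(), {"g1"})
        assert g.number_of_nodes() == 0

    def test_relaxing_dynamics_filter_only_adds_edges(self):
        rng = np.random.default_rng(4)
        peaks = [f"r{i}" for i in range(20)]
        hits = pd.DataFrame({
            "peak_id": peaks,
            "tf_id": [f"tf{i % 3}" for i in range(20)],
            "score": rng.uniform(5, 9, 20), "strand": "+",
        })
        pg = pd.DataFrame({"peak_id": peaks,
                           "gene_id": [f"g{i % 7}" for i in range(20)],
                           "distance": 100.0})
        tf_map = {"m1": {"tf0", "tf1"}, "m2": {"tf2"}}
        genes = {f"g{i}" for i in range(7)}
        strict = assemble_graph(tf_map, hits, pg, set(peaks[:5]), genes)
        loose = assemble_graph(tf_map, hits, pg, set(peaks), genes)
        assert set(strict.edges) <= set(loose.edges)

    def test_layering_invariant(self):
        g = assemble_graph({"m1": {"tf1"}}, self.HITS, self.PG, {"r1"}, {"g1"})
        order = {"mirna": 0, "tf": 1, "region": 2, "gene": 3}
        for u, v in g.edges:
            assert order[g.nodes[v]["node_type"]] - order[g.nodes[u]["node_type"]] == 1
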