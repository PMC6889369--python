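"""End-to-end orchestration of the analysis stages.

``run_all`` chains the full analysis on a simulated bundle: miRNA stage
enrichment, permutation repression screens (poly-miR vs control and islet vs
PE), direct-target calling, chromatin-layer assembly, edge/path/combined
scoring and top-k extraction.  Each stage is also callable on its own from
the library surface; ``run_all`` simply wires their inputs together and
collects the results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from mircade import chromatin, enrichment, scoring, screen, targets
from mircade.config import AnalysisConfig, SimulationConfig
from mircade.simulate import (
    ChromatinBundle,
    SequenceBundle,
    SyntheticTruth,
    as_comparison,
    plant_truth,
    simulate_chromatin_and_clip,
    simulate_expression_screens,
    simulate_small_rna_counts,
    synthesize_sequences,
)

logger = logging.getLogger(__name__)


def subseed(seed: int, stream: int) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    truth: SyntheticTruth
    sequences: SequenceBundle
    chromatin_bundle: ChromatinBundle
    ma_stats: pd.DataFrame
    enriched_mirnas: list[str]
    de_poly_down: pd.DataFrame
    de_poly_both: pd.DataFrame
    de_stage: pd.DataFrame
    repressed: set[str]
    regulated: set[str]
    stage_down: set[str]
    overlap_summary: screen.SetOverlap
    direct_calls: list[targets.DirectTargetCall]
    tf_map: dict[str, set[str]]
    tf_overlaps: pd.DataFrame
    peak_gene: pd.DataFrame
    dynamics: pd.DataFrame
    motif_hits: pd.DataFrame
    graph: nx.DiGraph
    histone_link: dict | None
    paths: list[scoring.ScoredPath]
    gene_scores: list[scoring.GeneScore]
    ranked: pd.DataFrame
    subnetwork: nx.DiGraph
    summary: dict = field(default_factory=dict)

    def cascade_recovery(self) -> float:
        """Fraction of distinct planted cascade genes in the final ranking."""
        planted = self.truth.cascade_genes
        if not planted:
            return float("nan")
        found = set(self.ranked["gene_id"]) & planted
        return len(found) / len(planted)


def run_all(
    sim_config: SimulationConfig,
    analysis: AnalysisConfig | None = None,
) -> PipelineResult:
    """Simulate a full input bundle and run every analysis stage on it."""
    cfg = analysis or AnalysisConfig()

    truth = plant_truth(sim_config)
    seqs = synthesize_sequences(truth, sim_config)
    counts = simulate_small_rna_counts(truth, sim_config)
    chrom = simulate_chromatin_and_clip(truth, sim_config, seqs)

    # stage 1: miRNA enrichment (endocrine over progenitor)
    ma = enrichment.compute_ma_stats(counts, "pe", "islet")
    enriched = enrichment.select_enriched(ma, cfg.min_reads, cfg.min_fold)
    logger.info("enriched miRNAs: %d selected", len(enriched))

    # stage 2: repression screens
    poly = as_comparison(
        simulate_expression_screens(truth, sim_config, "poly_mir"),
        simulate_expression_screens(truth, sim_config, "control"),
    )
    de_down = screen.permutation_de(
        poly, cfg.n_permutations, side="down", alpha=cfg.de_alpha,
        seed=subseed(cfg.seed, 1),
    )
    de_up = screen.permutation_de(
        poly, cfg.n_permutations, side="up", alpha=cfg.de_alpha,
        seed=subseed(cfg.seed, 1),
    )
    de_both = screen.permutation_de(
        poly, cfg.n_permutations, side="both", alpha=cfg.de_alpha,
        seed=subseed(cfg.seed, 2),
    )
    repressed = set(de_down.index[de_down["significant"]])
    # down- and up-regulated genes both enter the network layer
    regulated = repressed | set(de_up.index[de_up["significant"]])
    stage = as_comparison(
        simulate_expression_screens(truth, sim_config, "islet"),
        simulate_expression_screens(truth, sim_config, "pe"),
    )
    de_stage = screen.permutation_de(
        stage, cfg.n_permutations, side="both", alpha=cfg.de_alpha,
        seed=subseed(cfg.seed, 3),
    )
    stage_down = set(
        de_stage.index[de_stage["significant"] & (de_stage["direction"] == "down")]
    )
    overlap = screen.intersect_down_sets(repressed, stage_down)
    logger.info(
        "poly-miR repressed %d; stage-down %d; overlap %d (%.1f%%)",
        overlap.size_a, overlap.size_b, overlap.size_intersection, overlap.pct_of_a,
    )

    # stage 3: direct targets and the miRNA -> TF map
    sites: list[targets.SeedSite] = []
    for rec in seqs.mirna_records(enriched):
        sites.extend(targets.scan_seed_sites(rec, seqs.utr_seqs))
    clip_genes = targets.clip_gene_support(chrom.clip_peaks)
    if repressed:
        calls = targets.call_direct_targets(
            repressed, sites, clip_genes, mode=cfg.target_mode,
            tf_ids=set(truth.tfs),
        )
    else:
        logger.warning("no repressed genes; no direct targets callable")
        calls = []
    tf_map, tf_overlaps = targets.build_mirna_tf_map(calls, set(truth.tfs))

    # stage 4: chromatin layer and graph assembly
    peak_gene = chromatin.assign_peaks_to_tss(
        chrom.atac_peaks, seqs.tss, cfg.tss_max_distance, cfg.peak_fdr_max
    )
    dynamics = chromatin.classify_histone_dynamics(
        chrom.signal_frame("pe"), chrom.signal_frame("islet"),
        threshold=cfg.histone_log2fc_threshold,
    )
    dyn_peaks = chromatin.dynamic_peaks(dynamics)
    motif_hits = chromatin.scan_motifs(
        seqs.pwms, chrom.peak_sequences,
        score_threshold_quantile=cfg.motif_score_quantile,
        seed=subseed(cfg.seed, 4),
    )
    graph = chromatin.assemble_graph(tf_map, motif_hits, peak_gene, dyn_peaks, regulated)
    histone_link = None
    try:
        histone_link = chromatin.validate_histone_expression_link(
            dynamics, peak_gene, -de_stage["log2fc"]  # PE over islet
        )
    except ValueError as exc:
        logger.warning("histone-expression validation skipped: %s", exc)

    # stage 5: scoring and top-k extraction
    scoring.compute_edge_scores(graph, calls, motif_hits, de_both)
    paths = scoring.score_paths(graph)
    gene_scores = scoring.combined_gene_score(paths)
    ranked, subnet = scoring.extract_top_subnetwork(
        gene_scores, truth.cell_cycle_genes, k=cfg.top_k
    )

    result = PipelineResult(
        truth=truth,
        sequences=seqs,
        chromatin_bundle=chrom,
        ma_stats=ma,
        enriched_mirnas=enriched,
        de_poly_down=de_down,
        de_poly_both=de_both,
        de_stage=de_stage,
        repressed=repressed,
        regulated=regulated,
        stage_down=stage_down,
        overlap_summary=overlap,
        direct_calls=calls,
        tf_map=tf_map,
        tf_overlaps=tf_overlaps,
        peak_gene=peak_gene,
        dynamics=dynamics,
        motif_hits=motif_hits,
        graph=graph,
        histone_link=histone_link,
        paths=paths,
        gene_scores=gene_scores,
        ranked=ranked,
        subnetwork=subnet,
    )
    planted_enriched = set(truth.enriched_mirnas)
    result.summary = {
        "n_enriched_selected": len(enriched),
        "enriched_recovered": len(set(enriched) & planted_enriched),
        "n_planted_enriched": len(planted_enriched),
        "n_repressed": len(repressed),
        "n_regulated": len(regulated),
        "n_direct_calls": len(calls),
        "n_paths": len(paths),
        "n_scored_genes": len(gene_scores),
        "n_ranked": len(ranked),
        "cascade_recovery": result.cascade_recovery(),
    }
    logger.info("pipeline summary: %s", result.summary)
    return result
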