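"""Configuration objects for the simulator and the analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its stated domain."""


@dataclass
class SimulationConfig:
    """Parameters of the planted-truth simulation.

    The defaults define the study conditions used throughout the test suite:
    2,000 genes, 30 miRNA->TF->gene cascades driven by 4 stage-enriched
    miRNAs, -1 log2 direct repression, 3 biological replicates per group and
    negative-binomial count noise with dispersion 0.1.
    """

    n_genes: int = 2000
    n_mirnas: int = 100
    n_enriched: int = 4
    n_tfs: int = 8
    n_cascades: int = 30
    samples_per_group: int = 3
    sequencing_depth: int = 1_000_000
    nb_dispersion: float = 0.1
    effect_size_log2fc: float = -1.0
    utr_length: int = 500
    peak_width: int = 200
    genome_length: int = 60_000_000
    seed: int = 0

    # planted enrichment of induced miRNAs (raw endocrine-stage reads / fold)
    enriched_mean_reads: float = 20_000.0
    enriched_fold: float = 10.0
    background_mean_reads: float = 5_000.0

    # expression-screen noise and propagation
    expr_noise_sd_log2: float = 0.15
    indirect_fraction: float = 0.5

    # extra planted direct (non-TF) targets and negative controls
    n_direct_extra: int = 20
    n_decoy_peaks: int = 500
    dynamic_decoy_fraction: float = 0.1

    # chromatin / CLIP planting
    histone_log2_gap: float = 2.0
    clip_sensitivity: float = 0.3
    clip_fpr: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_enriched", "n_tfs",
                     "samples_per_group", "peak_width"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if self.n_cascades < 0:
            raise InvalidConfigError("n_cascades must be >= 0")
        if self.n_cascades > self.n_genes:
            raise InvalidConfigError("n_cascades cannot exceed n_genes")
        if self.n_enriched > self.n_mirnas:
            raise InvalidConfigError("n_enriched cannot exceed n_mirnas")
        if self.n_tfs >= self.n_genes:
            raise InvalidConfigError("n_tfs must be smaller than n_genes")
        if self.sequencing_depth <= 0:
            raise InvalidConfigError("sequencing_depth must be positive")
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be > 0")
        if self.utr_length < 8:
            raise InvalidConfigError("utr_length must be >= 8")
        if self.effect_size_log2fc > 0:
            raise InvalidConfigError("effect_size_log2fc is a repression (<= 0)")
        for name in ("clip_sensitivity", "clip_fpr", "dynamic_decoy_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        # every peak (placed within +/- max_peak_offset of its TSS) must stay
        # closest to its own TSS; see simulate.MAX_PEAK_OFFSET
        if self.tss_spacing < 2 * 12_000 + self.peak_width:
            raise InvalidConfigError(
                "genome_length too small to place peaks unambiguously "
                f"(TSS spacing {self.tss_spacing} bp)"
            )

    @property
    def tss_spacing(self) -> int:
        return self.genome_length // self.n_genes

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise InvalidConfigError(f"unknown simulation keys: {sorted(bad)}")
        return cls(**d)


@dataclass
class AnalysisConfig:
    """Thresholds of the analysis pipeline.

    Defaults mirror the published screen: miRNAs kept at > 5,000 raw
    endocrine-stage reads and > 2.3-fold induction; repression called at
    p < 0.05 by permutation test; ATAC peaks kept at FDR <= 0.01 and assigned
    to the closest TSS within 10 kb; the final ranking keeps the 40 highest
    scoring genes of the restriction set.
    """

    min_reads: float = 5000.0
    min_fold: float = 2.3
    de_alpha: float = 0.05
    n_permutations: int = 10_000
    tss_max_distance: int = 10_000
    peak_fdr_max: float = 0.01
    histone_log2fc_threshold: float = 1.0
    motif_score_quantile: float = 0.99
    top_k: int = 40
    seed: int = 0
    target_mode: str = "seed_or_clip"

    def __post_init__(self) -> None:
        if self.min_fold <= 0:
            raise InvalidConfigError("min_fold must be > 0")
        if not 0 < self.de_alpha < 1:
            raise InvalidConfigError("de_alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise InvalidConfigError("n_permutations must be >= 1")
        if self.tss_max_distance < 0:
            raise InvalidConfigError("tss_max_distance must be >= 0")
        if not 0 < self.peak_fdr_max <= 1:
            raise InvalidConfigError("peak_fdr_max must be in (0, 1]")
        if not 0 < self.motif_score_quantile < 1:
            raise InvalidConfigError("motif_score_quantile must be in (0, 1)")
        if self.top_k < 1:
            raise InvalidConfigError("top_k must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise InvalidConfigError(f"unknown analysis keys: {sorted(bad)}")
        return cls(**d)
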