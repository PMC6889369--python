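"""Planted-truth simulation of every pipeline input.

The generator emulates the data the analysis consumes: small-RNA count
tables for two stages (pancreatic endoderm "pe" and endocrine "islet"),
expression screens for miRNA over-expression and stage comparisons, miRNA
and 3'UTR sequences with embedded canonical seed sites, TF position weight
matrices, ATAC peaks with per-stage histone signal, and Argonaute-CLIP peaks
— together with the planted miRNA -> TF -> gene cascades needed for
parameter-recovery tests.

Statistical structure: negative-binomial counts with a shared dispersion for
the small-RNA tables; log-normal multiplicative noise around planted means
for RPKM-scale expression; cascades repress their TF by ``effect_size_log2fc``
directly and their downstream gene by ``indirect_fraction`` of it under the
poly-miR condition.  Every generator is bitwise deterministic for a fixed
seed (independent sub-streams per generator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mircade.chromatin import MARKS, GenomicInterval, tss_position
from mircade.config import InvalidConfigError, SimulationConfig
from mircade.enrichment import CountMatrix
from mircade.screen import ExpressionMatrix
from mircade.targets import MiRNARecord, reverse_complement

_DNA = np.array(list("ACGT"))
_RNA = np.array(list("ACGU"))
MAX_PEAK_OFFSET = 12_000  # decoy peaks may exceed the 10 kb assignment window
PWM_WIDTH = 8
PWM_CONSENSUS_PROB = 0.97


@dataclass(frozen=True)
class Cascade:
    mirna_id: str
    tf_id: str
    gene_id: str
    effect_log2fc: float  # planted direct repression of the TF, <= 0


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulation."""

    mirna_labels: dict[str, str]  # mirna -> enriched | background
    tfs: dict[str, str]  # tf gene id -> motif id
    cascades: list[Cascade]
    direct_extra: list[tuple[str, str, float]]  # (mirna, gene, effect)
    cell_cycle_genes: set[str]
    decoy_edges: list[tuple[str, str]]
    genes: list[str]
    seed: int

    @property
    def mirnas(self) -> list[str]:
        return list(self.mirna_labels)

    @property
    def enriched_mirnas(self) -> list[str]:
        return [m for m, lab in self.mirna_labels.items() if lab == "enriched"]

    @property
    def cascade_genes(self) -> set[str]:
        return {c.gene_id for c in self.cascades}

    def direct_pairs(self) -> dict[tuple[str, str], float]:
        """Planted direct (miRNA, gene) repressions, TFs and extras."""
        pairs: dict[tuple[str, str], float] = {}
        for c in self.cascades:
            key = (c.mirna_id, c.tf_id)
            pairs[key] = min(pairs.get(key, 0.0), c.effect_log2fc)
        for m, g, eff in self.direct_extra:
            pairs[(m, g)] = min(pairs.get((m, g), 0.0), eff)
        return pairs

    def multi_mirna_genes(self) -> set[str]:
        by_gene: dict[str, set[str]] = {}
        for c in self.cascades:
            by_gene.setdefault(c.gene_id, set()).add(c.mirna_id)
        return {g for g, ms in by_gene.items() if len(ms) > 1}


def _rng(stream: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


def plant_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw the planted cascades, labels and gene sets for one simulation."""
    rng = _rng(0, config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    tf_idx = sorted(rng.choice(config.n_genes, size=config.n_tfs, replace=False))
    tfs = {genes[i]: f"M{k:02d}" for k, i in enumerate(tf_idx)}
    mirnas = [f"miR-{i + 1:02d}" for i in range(config.n_mirnas)]
    labels = {
        m: ("enriched" if i < config.n_enriched else "background")
        for i, m in enumerate(mirnas)
    }
    enriched = [m for m in mirnas if labels[m] == "enriched"]

    candidates = [g for g in genes if g not in tfs]
    pool_size = min(len(candidates), max(1, round(0.75 * config.n_cascades)))
    cascades: list[Cascade] = []
    if config.n_cascades > 0:
        if config.n_enriched * pool_size < config.n_cascades:
            raise InvalidConfigError("too few genes/miRNAs for requested cascades")
        pool = sorted(rng.choice(candidates, size=pool_size, replace=False))
        used: set[tuple[str, str]] = set()
        attempts = 0
        while len(cascades) < config.n_cascades:
            attempts += 1
            if attempts > 100_000:  # pragma: no cover
                raise InvalidConfigError("could not place distinct cascades")
            m = enriched[rng.integers(len(enriched))]
            tf = list(tfs)[rng.integers(len(tfs))]
            g = pool[rng.integers(len(pool))]
            if (m, g) in used:
                continue
            used.add((m, g))
            cascades.append(Cascade(m, tf, g, config.effect_size_log2fc))

    cascade_genes = {c.gene_id for c in cascades}
    spare = [g for g in candidates if g not in cascade_genes]
    n_extra = min(config.n_direct_extra, max(0, len(spare) - len(cascade_genes)))
    extra_pick = sorted(rng.choice(spare, size=n_extra, replace=False)) if n_extra else []
    direct_extra = [
        (enriched[rng.integers(len(enriched))] if enriched else mirnas[0], g,
         config.effect_size_log2fc)
        for g in extra_pick
    ]
    extra_genes = {g for _, g, _ in direct_extra}

    decoy_pool = [g for g in spare if g not in extra_genes]
    n_cc_decoys = min(len(decoy_pool), max(1, len(cascade_genes)))
    cc_decoys = sorted(rng.choice(decoy_pool, size=n_cc_decoys, replace=False))
    cell_cycle = cascade_genes | set(cc_decoys)

    planted_pairs = set(SyntheticTruth(
        labels, tfs, cascades, direct_extra, set(), [], genes, config.seed
    ).direct_pairs())
    decoy_edges = []
    while len(decoy_edges) < min(20, len(decoy_pool)):
        m = mirnas[rng.integers(len(mirnas))]
        g = decoy_pool[rng.integers(len(decoy_pool))]
        if (m, g) not in planted_pairs and (m, g) not in decoy_edges:
            decoy_edges.append((m, g))

    return SyntheticTruth(
        mirna_labels=labels,
        tfs=tfs,
        cascades=cascades,
        direct_extra=direct_extra,
        cell_cycle_genes=cell_cycle,
        decoy_edges=decoy_edges,
        genes=genes,
        seed=config.seed,
    )


@dataclass
class SequenceBundle:
    """Sequences, TSS annotation and PWMs generated for one truth."""

    mirna_seqs: dict[str, str]  # RNA, 5'->3'
    utr_seqs: dict[str, str]  # DNA, sense strand
    tss: list[GenomicInterval]
    pwms: dict[str, np.ndarray]  # tf gene id -> 4 x width probability matrix
    consensus: dict[str, str]
    planted_sites: list[tuple[str, str, int]]  # (mirna, gene, utr position)

    def mirna_records(self, ids=None) -> list[MiRNARecord]:
        ids = list(self.mirna_seqs) if ids is None else ids
        return [MiRNARecord(m, self.mirna_seqs[m]) for m in ids]


def _random_seq(rng: np.random.Generator, n: int, alphabet=_DNA) -> str:
    return "".join(alphabet[rng.integers(4, size=n)])


def _avoid_patterns(mirna_seqs: dict[str, str], enriched: list[str]) -> list[str]:
    """Substrings whose absence guarantees zero canonical sites for the
    enriched miRNAs (the 7mer-m8 core and the 7mer-A1 pattern cover all
    three site types)."""
    pats = []
    for m in enriched:
        m7 = reverse_complement(mirna_seqs[m][1:8])
        pats.extend([m7, m7[1:] + "A"])
    return pats


def synthesize_sequences(
    truth: SyntheticTruth, config: SimulationConfig
) -> SequenceBundle:
    """Generate miRNA/UTR sequences, TSS annotation and TF PWMs.

    Every planted direct (miRNA, gene) pair receives one embedded 8mer site
    (reverse complement of seed nt 2-8 followed by A) in that gene's UTR;
    all other UTRs are rejection-sampled to carry no canonical site of any
    enriched miRNA (at most 1,000 attempts per UTR).
    """
    rng = _rng(1, config.seed)

    mirna_seqs: dict[str, str] = {}
    seen_seeds: set[str] = set()
    for m in truth.mirnas:
        for _ in range(1000):
            seq = _random_seq(rng, 22, _RNA)
            if seq[1:8] not in seen_seeds:
                break
        else:  # pragma: no cover
            raise InvalidConfigError("could not draw distinct miRNA seeds")
        seen_seeds.add(seq[1:8])
        mirna_seqs[m] = seq

    consensus: dict[str, str] = {}
    seen_cons: set[str] = set()
    for tf in truth.tfs:
        for _ in range(1000):
            c = _random_seq(rng, PWM_WIDTH)
            if c not in seen_cons:
                break
        seen_cons.add(c)
        consensus[tf] = c
    pwms = {}
    for tf, cons in consensus.items():
        m = np.full((4, PWM_WIDTH), (1 - PWM_CONSENSUS_PROB) / 3)
        for j, base in enumerate(cons):
            m["ACGT".index(base), j] = PWM_CONSENSUS_PROB
        pwms[tf] = m

    enriched = truth.enriched_mirnas
    avoid = _avoid_patterns(mirna_seqs, enriched)
    planted_by_gene: dict[str, list[str]] = {}
    for (m, g) in truth.direct_pairs():
        planted_by_gene.setdefault(g, []).append(m)

    utr_seqs: dict[str, str] = {}
    planted_sites: list[tuple[str, str, int]] = []
    for gene in truth.genes:
        planted = sorted(set(planted_by_gene.get(gene, [])))
        for _ in range(1000):
            seq = _random_seq(rng, config.utr_length)
            if any(p in seq for p in avoid):
                continue
            if not planted:
                break
            if config.utr_length < 8 * len(planted):
                raise InvalidConfigError("utr_length too short for planted sites")
            # one 8mer per planted miRNA in its own segment of the UTR
            seg = config.utr_length // len(planted)
            chars = list(seq)
            positions = []
            for k, m in enumerate(planted):
                site = reverse_complement(mirna_seqs[m][1:8]) + "A"
                lo = k * seg
                hi = min((k + 1) * seg, config.utr_length) - 8
                pos = int(rng.integers(lo, hi + 1))
                chars[pos:pos + 8] = site
                positions.append((m, pos))
            seq = "".join(chars)
            # embedding may create junction sites for other enriched miRNAs
            other = [
                p for m in enriched if m not in planted
                for p in _avoid_patterns(mirna_seqs, [m])
            ]
            if not any(p in seq for p in other):
                break
        else:
            raise InvalidConfigError(f"rejection sampling failed for UTR of {gene}")
        utr_seqs[gene] = seq
        for m, pos in (positions if planted else []):
            planted_sites.append((m, gene, pos))

    spacing = config.tss_spacing
    tss = [
        GenomicInterval(
            "chr1",
            spacing // 2 + i * spacing,
            spacing // 2 + i * spacing + 1,
            gene,
            strand="+" if i % 2 == 0 else "-",
        )
        for i, gene in enumerate(truth.genes)
    ]
    return SequenceBundle(mirna_seqs, utr_seqs, tss, pwms, consensus, planted_sites)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_small_rna_counts(
    truth: SyntheticTruth, config: SimulationConfig
) -> CountMatrix:
    """Negative-binomial small-RNA counts for the two stages.

    Enriched miRNAs receive an endocrine-stage mean of
    ``enriched_mean_reads`` and a PE mean lower by ``enriched_fold``;
    background miRNAs share one log-normal baseline across stages.
    """
    if config.sequencing_depth <= 0:
        raise InvalidConfigError("sequencing_depth must be positive")
    rng = _rng(2, config.seed)
    n = config.samples_per_group
    samples = [f"pe_{i + 1}" for i in range(n)] + [f"islet_{i + 1}" for i in range(n)]
    stages = {s: ("pe" if s.startswith("pe") else "islet") for s in samples}
    rows = []
    for m in truth.mirnas:
        if truth.mirna_labels[m] == "enriched":
            mu_islet = config.enriched_mean_reads
            mu_pe = config.enriched_mean_reads / config.enriched_fold
        else:
            mu_pe = mu_islet = float(
                rng.lognormal(math.log(config.background_mean_reads), 0.5)
            )
        pe = _nb_draw(rng, mu_pe, config.nb_dispersion, n)
        islet = _nb_draw(rng, mu_islet, config.nb_dispersion, n)
        rows.append(np.concatenate([pe, islet]))
    counts = pd.DataFrame(rows, index=pd.Index(truth.mirnas, name="mirna_id"),
                          columns=samples)
    return CountMatrix(counts, stages)


_CONDITION_CODES = {"control": 0, "poly_mir": 1, "pe": 2, "islet": 3}


def baseline_gene_means(truth: SyntheticTruth, config: SimulationConfig) -> pd.Series:
    """Per-gene baseline RPKM-scale means, shared across all conditions."""
    rng = _rng(4, config.seed)
    base = rng.lognormal(math.log(20.0), 1.0, size=len(truth.genes))
    return pd.Series(base, index=truth.genes)


def _planted_shifts(truth: SyntheticTruth, config: SimulationConfig,
                    condition: str) -> pd.Series:
    shifts = pd.Series(0.0, index=truth.genes)
    pairs = truth.direct_pairs()
    if condition in ("control", "pe"):
        return shifts
    if condition == "poly_mir":
        for (m, g), eff in pairs.items():
            shifts[g] = min(shifts[g], eff)
        for c in truth.cascades:
            indirect = config.indirect_fraction * c.effect_log2fc
            shifts[c.gene_id] = min(shifts[c.gene_id], indirect)
        return shifts
    if condition == "islet":
        for (m, g), eff in pairs.items():
            shifts[g] = min(shifts[g], eff)
        for c in truth.cascades:
            shifts[c.gene_id] = min(shifts[c.gene_id], c.effect_log2fc)
        return shifts
    if condition in truth.mirna_labels:  # single-miRNA over-expression
        for (m, g), eff in pairs.items():
            if m == condition:
                shifts[g] = min(shifts[g], eff)
        return shifts
    raise ValueError(f"unknown condition label: {condition!r}")


def simulate_expression_screens(
    truth: SyntheticTruth,
    config: SimulationConfig,
    condition: str,
) -> ExpressionMatrix:
    """RPKM-scale expression of one condition (``samples_per_group`` samples).

    ``condition`` is one of ``control``, ``poly_mir``, ``pe``, ``islet`` or a
    miRNA id (single-miRNA over-expression).  Values are the baseline means
    times ``2**shift`` for planted genes, with log-normal noise of
    ``expr_noise_sd_log2`` log2 units.
    """
    shifts = _planted_shifts(truth, config, condition)
    code = _CONDITION_CODES.get(condition)
    if code is None:
        code = 10 + truth.mirnas.index(condition)
    rng = _rng(3 * 1000 + code, config.seed)
    base = baseline_gene_means(truth, config)
    mu = base.to_numpy() * np.power(2.0, shifts.to_numpy())
    n = config.samples_per_group
    noise = np.power(
        2.0, rng.normal(0.0, config.expr_noise_sd_log2, size=(len(mu), n))
    )
    values = pd.DataFrame(
        mu[:, None] * noise,
        index=pd.Index(truth.genes, name="gene_id"),
        columns=[f"{condition.replace(':', '_')}_{i + 1}" for i in range(n)],
    )
    labels = {s: condition for s in values.columns}
    return ExpressionMatrix(values, labels)


def as_comparison(case: ExpressionMatrix, control: ExpressionMatrix) -> ExpressionMatrix:
    """Combine two single-condition matrices into one case/control matrix."""
    overlap = set(case.values.columns) & set(control.values.columns)
    if overlap:
        raise ValueError(f"sample-id collision between conditions: {sorted(overlap)}")
    values = pd.concat([case.values, control.values], axis=1)
    labels = {s: "case" for s in case.values.columns}
    labels.update({s: "control" for s in control.values.columns})
    return ExpressionMatrix(values, labels)


@dataclass
class ChromatinBundle:
    """ATAC peaks (with FDR), their sequences, per-stage histone signal and
    CLIP peaks in UTR coordinates."""

    atac_peaks: list[GenomicInterval]
    peak_sequences: dict[str, str]
    histone: dict[tuple[str, str], pd.Series]  # (mark, stage) -> peak signal
    clip_peaks: list[GenomicInterval]

    def signal_frame(self, stage: str) -> pd.DataFrame:
        return pd.DataFrame({mark: self.histone[(mark, stage)] for mark in MARKS})


def simulate_chromatin_and_clip(
    truth: SyntheticTruth,
    config: SimulationConfig,
    sequences: SequenceBundle | None = None,
) -> ChromatinBundle:
    """ATAC peaks, histone signal and CLIP peaks consistent with the truth.

    Every cascade receives one peak within 2 kb of its gene's TSS carrying
    the cascade TF's motif consensus and a planted PE-up histone gap of
    ``histone_log2_gap`` log2 units on both marks (the gene is islet-down).
    Decoy peaks are placed up to +/-12 kb from random TSSs with mostly
    stable histone signal.  CLIP peaks cover ``clip_sensitivity`` of planted
    seed sites plus a ``clip_fpr`` false-positive rate on other genes.
    """
    rng = _rng(5, config.seed)
    seqs = sequences if sequences is not None else synthesize_sequences(truth, config)
    tss_of = {t.name: tss_position(t) for t in seqs.tss}
    width = config.peak_width
    if config.tss_spacing < 2 * MAX_PEAK_OFFSET + width:
        raise InvalidConfigError("genome_length too small to place peaks")

    peaks: list[GenomicInterval] = []
    peak_seq: dict[str, str] = {}
    hist: dict[tuple[str, str], dict[str, float]] = {
        (mark, stage): {} for mark in MARKS for stage in ("pe", "islet")
    }

    def add_histone(pid: str, log2_gap: float) -> None:
        for mark in MARKS:
            base = float(rng.lognormal(math.log(10.0), 0.3))
            noise = lambda: float(rng.lognormal(0.0, 0.1))
            hist[(mark, "islet")][pid] = base * noise()
            hist[(mark, "pe")][pid] = base * (2.0 ** log2_gap) * noise()

    for i, c in enumerate(truth.cascades):
        pid = f"peak_c{i:03d}"
        center = tss_of[c.gene_id] + int(rng.integers(-2000, 2001))
        start = max(0, center - width // 2)
        seq = list(_random_seq(rng, width))
        cons = seqs.consensus[c.tf_id]
        off = int(rng.integers(0, width - len(cons) + 1))
        seq[off:off + len(cons)] = cons
        peaks.append(GenomicInterval("chr1", start, start + width, pid,
                                     score=float(rng.uniform(0.0, 0.005))))
        peak_seq[pid] = "".join(seq)
        add_histone(pid, config.histone_log2_gap)  # PE-up: gene is islet-down

    for i in range(config.n_decoy_peaks):
        pid = f"peak_d{i:04d}"
        gene = truth.genes[int(rng.integers(len(truth.genes)))]
        center = tss_of[gene] + int(rng.integers(-MAX_PEAK_OFFSET, MAX_PEAK_OFFSET + 1))
        start = max(0, center - width // 2)
        peaks.append(GenomicInterval("chr1", start, start + width, pid,
                                     score=float(rng.uniform(0.0, 0.02))))
        peak_seq[pid] = _random_seq(rng, width)
        if rng.random() < config.dynamic_decoy_fraction:
            gap = config.histone_log2_gap * (1 if rng.random() < 0.5 else -1)
            add_histone(pid, gap)
        else:
            add_histone(pid, 0.0)

    clip: list[GenomicInterval] = []
    planted_genes = set()
    for m, gene, pos in seqs.planted_sites:
        planted_genes.add(gene)
        if rng.random() < config.clip_sensitivity:
            start = max(0, pos - 4)
            end = min(len(seqs.utr_seqs[gene]), pos + 12)
            clip.append(GenomicInterval(gene, start, end, f"clip_{gene}_{pos}"))
    for gene in truth.genes:
        if gene in planted_genes:
            continue
        if rng.random() < config.clip_fpr:
            start = int(rng.integers(0, max(1, config.utr_length - 20)))
            clip.append(GenomicInterval(gene, start, start + 20, f"clip_fp_{gene}"))

    histone = {
        key: pd.Series(vals, name=key[0]).sort_index()
        for key, vals in hist.items()
    }
    return ChromatinBundle(peaks, peak_seq, histone, clip)
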