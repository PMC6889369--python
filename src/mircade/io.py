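"""Readers and writers for the pipeline's file formats.

Formats: FASTA (miRNA and UTR sequences, via Biopython), BED6 (0-based
half-open intervals; TSS, ATAC, CLIP), TSV matrices (first column feature
id, header row sample ids), a minimal MEME-style PWM text format, GMT-like
gene-set TSV (name, description, tab-separated gene ids) and JSON/TSV
network outputs.  Readers validate their inputs and fail with errors naming
the offending file and line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mircade.chromatin import GenomicInterval
from mircade.config import AnalysisConfig, SimulationConfig
from mircade.enrichment import CountMatrix
from mircade.scoring import GeneScore, scores_table
from mircade.simulate import (
    Cascade,
    ChromatinBundle,
    SequenceBundle,
    SyntheticTruth,
)

logger = logging.getLogger(__name__)


# --- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --- BED6 -------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            name = parts[3] if len(parts) > 3 else "."
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
            intervals.append(GenomicInterval(parts[0], start, end, name, score, strand))
    logger.info("read %d intervals from %s", len(intervals), path)
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else repr(iv.score)
            strand = iv.strand if iv.strand else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{strand}\n"
            )


# --- TSV matrices -----------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no features")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    logger.info("read %d x %d matrix from %s", *df.shape, path)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, label) -> dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample, label)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_sample_sheet(labels: dict[str, str], path: str | Path,
                       label_name: str = "stage") -> None:
    pd.DataFrame(
        {"sample": list(labels), label_name: list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_count_matrix(matrix_path: str | Path, sheet_path: str | Path) -> CountMatrix:
    counts = read_matrix(matrix_path)
    labels = read_sample_sheet(sheet_path)
    missing = [s for s in counts.columns if s not in labels]
    if missing:
        raise ValueError(
            f"{sheet_path}: samples missing from sample sheet: {missing}"
        )
    return CountMatrix(counts, {s: labels[s] for s in counts.columns})


# --- minimal MEME-style PWMs ------------------------------------------------

def write_meme(pwms: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for name, m in pwms.items():
            m = np.asarray(m, float)
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.shape[1]} "
                f"nsites= 20 E= 0\n"
            )
            for col in m.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> dict[str, np.ndarray]:
    pwms: dict[str, np.ndarray] = {}
    name = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    pwms[name] = np.array(rows).T
                name = line.split()[1]
                rows = []
            elif name is not None and line and line[0].isdigit():
                rows.append([float(x) for x in line.split()])
    if name is not None and rows:
        pwms[name] = np.array(rows).T
    for nm, m in pwms.items():
        if m.shape[0] != 4 or not np.allclose(m.sum(axis=0), 1.0, atol=1e-4):
            raise ValueError(f"{path}: PWM {nm}: columns must sum to 1")
    return pwms


# --- GMT-like gene sets -----------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected name, description, genes"
                )
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              description: str = "mircade") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description] + sorted(genes)) + "\n")


# --- truth JSON -------------------------------------------------------------

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    doc = {
        "mirna_labels": truth.mirna_labels,
        "tfs": truth.tfs,
        "cascades": [asdict(c) for c in truth.cascades],
        "direct_extra": [list(t) for t in truth.direct_extra],
        "cell_cycle_genes": sorted(truth.cell_cycle_genes),
        "decoy_edges": [list(t) for t in truth.decoy_edges],
        "genes": truth.genes,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> SyntheticTruth:
    doc = json.loads(Path(path).read_text())
    return SyntheticTruth(
        mirna_labels=doc["mirna_labels"],
        tfs=doc["tfs"],
        cascades=[Cascade(**c) for c in doc["cascades"]],
        direct_extra=[tuple(t) for t in doc["direct_extra"]],
        cell_cycle_genes=set(doc["cell_cycle_genes"]),
        decoy_edges=[tuple(t) for t in doc["decoy_edges"]],
        genes=doc["genes"],
        seed=doc["seed"],
    )


# --- simulation bundle on disk ----------------------------------------------

def write_simulation(
    out_dir: str | Path,
    truth: SyntheticTruth,
    sequences: SequenceBundle,
    counts: CountMatrix,
    chromatin: ChromatinBundle,
    expression: dict[str, pd.DataFrame] | None = None,
) -> None:
    """Serialize a complete simulated input bundle into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_truth(truth, out / "truth.json")
    write_fasta(sequences.mirna_seqs, out / "mirnas.fa")
    write_fasta(sequences.utr_seqs, out / "utrs.fa")
    write_bed(sequences.tss, out / "tss.bed")
    write_meme(
        {truth.tfs[tf]: m for tf, m in sequences.pwms.items()}, out / "pwms.meme"
    )
    pd.DataFrame(
        {"tf": list(truth.tfs), "motif": list(truth.tfs.values())}
    ).to_csv(out / "tfs.tsv", sep="\t", index=False)
    write_matrix(counts.counts, out / "small_rna_counts.tsv")
    write_sample_sheet(counts.stage_labels, out / "small_rna_samples.tsv")
    write_bed(chromatin.atac_peaks, out / "atac.bed")
    write_fasta(chromatin.peak_sequences, out / "peak_sequences.fa")
    for (mark, stage), series in chromatin.histone.items():
        series.rename("signal").to_frame().rename_axis("peak_id").to_csv(
            out / f"histone_{mark}_{stage}.tsv", sep="\t"
        )
    write_bed(chromatin.clip_peaks, out / "clip.bed")
    write_gmt({"cell_cycle": truth.cell_cycle_genes}, out / "gene_sets.gmt")
    for name, df in (expression or {}).items():
        write_matrix(df, out / f"expression_{name}.tsv")


@dataclass
class InputBundle:
    """Validated in-memory pipeline inputs, as loaded from disk."""

    mirna_seqs: dict[str, str]
    utr_seqs: dict[str, str]
    tss: list[GenomicInterval]
    pwms: dict[str, np.ndarray]
    tfs: dict[str, str]
    counts: CountMatrix
    atac_peaks: list[GenomicInterval]
    peak_sequences: dict[str, str]
    histone: dict[tuple[str, str], pd.Series]
    clip_peaks: list[GenomicInterval]
    gene_sets: dict[str, set[str]]
    expression: dict[str, pd.DataFrame] = field(default_factory=dict)


def load_inputs_bundle(in_dir: str | Path) -> InputBundle:
    """Load and validate a simulated (or equivalently structured) bundle."""
    d = Path(in_dir)
    tf_df = pd.read_csv(d / "tfs.tsv", sep="\t", dtype=str)
    tfs = dict(zip(tf_df["tf"], tf_df["motif"]))
    motif_pwms = read_meme(d / "pwms.meme")
    by_motif = {v: k for k, v in tfs.items()}
    pwms = {by_motif.get(name, name): m for name, m in motif_pwms.items()}
    histone = {}
    for f in sorted(d.glob("histone_*_*.tsv")):
        _, mark, stage = f.stem.split("_")
        histone[(mark, stage)] = read_matrix(f)["signal"]
    expression = {}
    for f in sorted(d.glob("expression_*.tsv")):
        expression[f.stem.removeprefix("expression_")] = read_matrix(f)
    return InputBundle(
        mirna_seqs=read_fasta(d / "mirnas.fa"),
        utr_seqs=read_fasta(d / "utrs.fa"),
        tss=read_bed(d / "tss.bed"),
        pwms=pwms,
        tfs=tfs,
        counts=read_count_matrix(d / "small_rna_counts.tsv",
                                 d / "small_rna_samples.tsv"),
        atac_peaks=read_bed(d / "atac.bed"),
        peak_sequences=read_fasta(d / "peak_sequences.fa"),
        histone=histone,
        clip_peaks=read_bed(d / "clip.bed"),
        gene_sets=read_gmt(d / "gene_sets.gmt"),
        expression=expression,
    )


# --- network outputs --------------------------------------------------------

def write_network_outputs(
    graph: nx.DiGraph,
    scores: list[GeneScore],
    out_dir: str | Path,
) -> None:
    """Write the edge list, node table and ranked gene scores.

    The gene-score TSV is sorted by combined score descending with ties
    broken by gene id ascending; re-loading reproduces the graph exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        (u, v, f"{d['layer']}-edge", d["layer"], d.get("score"))
        for u, v, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(
        rows, columns=["source", "target", "edge_type", "layer", "score"]
    ).to_csv(out / "network_edges.tsv", sep="\t", index=False)
    nodes = {n: d["node_type"] for n, d in graph.nodes(data=True)}
    (out / "network_nodes.json").write_text(json.dumps(nodes, indent=1, sort_keys=True))
    table = scores_table(
        sorted(scores, key=lambda g: (-g.combined, g.gene_id))
    )
    table.to_csv(out / "gene_scores.tsv", sep="\t", index=False)


def read_network(out_dir: str | Path) -> nx.DiGraph:
    out = Path(out_dir)
    nodes = json.loads((out / "network_nodes.json").read_text())
    edges = pd.read_csv(out / "network_edges.tsv", sep="\t")
    g = nx.DiGraph()
    for n, t in nodes.items():
        g.add_node(n, node_type=t)
    for _, r in edges.iterrows():
        attrs = {"layer": r["layer"]}
        if pd.notna(r["score"]):
            attrs["score"] = float(r["score"])
        g.add_edge(r["source"], r["target"], **attrs)
    return g


# --- configuration ----------------------------------------------------------

def load_config(path: str | Path) -> tuple[SimulationConfig, AnalysisConfig]:
    """Load a YAML config with optional ``simulation`` and ``analysis``
    sections; omitted keys keep their defaults."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    sim = SimulationConfig.from_dict(doc.get("simulation", {}))
    ana = AnalysisConfig.from_dict(doc.get("analysis", {}))
    return sim, ana
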