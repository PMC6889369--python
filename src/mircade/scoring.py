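"""Edge, path and combined gene scoring of the regulatory graph.

Every miRNA -> TF -> region -> gene path carries three edge scores in [0, 1]:

* ``a`` (miRNA -> TF): seed-site strength (8mer = 1, 7mer-m8 = 2/3,
  7mer-A1 = 1/3, best site counts) and Argonaute-CLIP support, weighted
  half-and-half;
* ``b`` (TF -> region): best motif log-odds, min-max normalised within each
  PWM so that scores are comparable across motifs of different information
  content;
* ``c`` (region -> gene): strength of the gene's differential regulation,
  ``min(1, -log10(p) / 4)``.

The path score is the plain sum ``s = a + b + c``; the combined gene score
sums, over the distinct miRNAs reaching a gene, each miRNA's best path score,
so genes under the control of several miRNAs outrank genes reached equally
strongly by a single miRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from mircade.targets import DirectTargetCall

logger = logging.getLogger(__name__)

SITE_STRENGTH = {"8mer": 1.0, "7mer-m8": 2.0 / 3.0, "7mer-A1": 1.0 / 3.0}


@dataclass(frozen=True)
class ScoredPath:
    mirna_id: str
    tf_id: str
    region_id: str
    gene_id: str
    a: float
    b: float
    c: float
    s: float  # a + b + c, computed once at construction


@dataclass
class GeneScore:
    gene_id: str
    combined: float
    contributing_mirnas: set[str]
    best_paths: dict[str, ScoredPath]  # mirna -> its best path to this gene


def compute_edge_scores(
    graph: nx.DiGraph,
    target_evidence: list[DirectTargetCall],
    motif_hits: pd.DataFrame,
    de_results: pd.DataFrame,
    neglog10_cap: float = 4.0,
) -> nx.DiGraph:
    """Attach a ``score`` in [0, 1] to every edge of the assembled graph."""
    evidence = {c.gene_id: c for c in target_evidence}
    # per-PWM min-max over all hits of that PWM (degenerate range -> 1.0)
    ranges = motif_hits.groupby("tf_id")["score"].agg(["min", "max"])

    for u, v, data in graph.edges(data=True):
        layer = data["layer"]
        if layer == "a":
            call = evidence.get(v)
            if call is None:
                raise ValueError(f"a-edge {u}->{v}: no direct-target evidence")
            strength = SITE_STRENGTH.get(call.site_types.get(u), 0.0)
            clip = 1.0 if call.evidence in ("seed_and_clip", "clip_only") else 0.0
            score = 0.5 * strength + 0.5 * clip
        elif layer == "b":
            if u not in ranges.index:
                raise ValueError(f"b-edge {u}->{v}: no motif hit record")
            raw = data.get("motif_score")
            if raw is None:
                match = motif_hits[
                    (motif_hits["tf_id"] == u) & (motif_hits["peak_id"] == v)
                ]
                if match.empty:
                    raise ValueError(f"b-edge {u}->{v}: no motif hit record")
                raw = float(match["score"].max())
            lo, hi = ranges.loc[u, "min"], ranges.loc[u, "max"]
            score = 1.0 if hi <= lo else (raw - lo) / (hi - lo)
        elif layer == "c":
            if v not in de_results.index:
                raise ValueError(f"c-edge {u}->{v}: gene missing from DE results")
            p = float(de_results.loc[v, "p_value"])
            score = min(1.0, -np.log10(max(p, 1e-300)) / neglog10_cap)
        else:  # pragma: no cover
            raise ValueError(f"unknown edge layer {layer!r}")
        data["score"] = float(min(1.0, max(0.0, score)))
    return graph


def score_paths(graph: nx.DiGraph) -> list[ScoredPath]:
    """Enumerate every four-layer path and score it as s = a + b + c."""
    paths = []
    for mirna, tf, a_data in graph.edges(data=True):
        if a_data["layer"] != "a":
            continue
        a = a_data["score"]
        for _, region, b_data in graph.edges(tf, data=True):
            if b_data["layer"] != "b":
                continue
            b = b_data["score"]
            for _, gene, c_data in graph.edges(region, data=True):
                if c_data["layer"] != "c":
                    continue
                c = c_data["score"]
                paths.append(
                    ScoredPath(mirna, tf, region, gene, a, b, c, a + b + c)
                )
    return paths


def combined_gene_score(paths: list[ScoredPath]) -> list[GeneScore]:
    """Per-gene combined score: sum over distinct miRNAs of that miRNA's
    maximum path score to the gene.

    Best-path ties within a miRNA are broken by (tf, region) ascending for
    determinism.  The result is sorted by combined score descending, ties by
    gene id ascending.
    """
    per_gene: dict[str, dict[str, ScoredPath]] = {}
    for p in paths:
        best = per_gene.setdefault(p.gene_id, {})
        cur = best.get(p.mirna_id)
        if (cur is None or p.s > cur.s
                or (p.s == cur.s and (p.tf_id, p.region_id) < (cur.tf_id, cur.region_id))):
            best[p.mirna_id] = p
    scores = [
        GeneScore(
            gene_id=gene,
            combined=sum(p.s for p in best.values()),
            contributing_mirnas=set(best),
            best_paths=dict(sorted(best.items())),
        )
        for gene, best in per_gene.items()
    ]
    scores.sort(key=lambda g: (-g.combined, g.gene_id))
    return scores


def scores_table(scores: list[GeneScore]) -> pd.DataFrame:
    rows = [
        (
            g.gene_id,
            g.combined,
            len(g.contributing_mirnas),
            ";".join(
                f"{m}>{p.tf_id}>{p.region_id}:{p.s:.4f}"
                for m, p in g.best_paths.items()
            ),
        )
        for g in scores
    ]
    return pd.DataFrame(rows, columns=["gene_id", "combined", "n_mirnas", "best_paths"])


def extract_top_subnetwork(
    scores: list[GeneScore],
    restrict_to: set[str] | None = None,
    k: int = 40,
    graph: nx.DiGraph | None = None,
) -> tuple[pd.DataFrame, nx.DiGraph]:
    """Top-k ranked genes (optionally restricted to a gene set, e.g. cell
    cycle) and the induced subgraph of their best paths.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    kept = [g for g in scores if restrict_to is None or g.gene_id in restrict_to]
    if restrict_to is not None and not kept:
        logger.warning("restriction set is disjoint from the scored genes")
    kept.sort(key=lambda g: (-g.combined, g.gene_id))
    kept = kept[:k]
    sub = nx.DiGraph()
    for g in kept:
        for mirna, p in g.best_paths.items():
            sub.add_node(p.mirna_id, node_type="mirna")
            sub.add_node(p.tf_id, node_type="tf")
            sub.add_node(p.region_id, node_type="region")
            sub.add_node(p.gene_id, node_type="gene")
            sub.add_edge(p.mirna_id, p.tf_id, layer="a", score=p.a)
            sub.add_edge(p.tf_id, p.region_id, layer="b", score=p.b)
            sub.add_edge(p.region_id, p.gene_id, layer="c", score=p.c)
    return scores_table(kept), sub
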