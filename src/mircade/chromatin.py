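"""Chromatin-layer operations and assembly of the four-layer regulatory graph.

Open-chromatin (ATAC) peaks become candidate TF-binding regions when they
(i) pass the peak-calling FDR filter, (ii) lie within ``max_distance`` of the
closest TSS of a differentially regulated gene, (iii) show histone-mark
dynamics (H3K4me3 / H3K27ac) between the two stages, and (iv) carry a motif
of a miRNA-targeted TF.  The resulting graph has four strict layers —
miRNA -> TF -> region -> gene — with edge types a, b, c.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

MARKS = ("H3K4me3", "H3K27ac")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None  # peak FDR where applicable
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.name} ({self.chrom}): start {self.start} >= end {self.end}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def tss_position(tss: GenomicInterval) -> int:
    """Strand-aware TSS coordinate: ``start`` on +, ``end - 1`` on -."""
    return tss.start if tss.strand != "-" else tss.end - 1


def assign_peaks_to_tss(
    peaks: list[GenomicInterval],
    tss: list[GenomicInterval],
    max_distance: int = 10_000,
    peak_fdr_max: float | None = None,
) -> pd.DataFrame:
    """Assign each peak to the single closest TSS by |midpoint - TSS|.

    Peaks farther than ``max_distance`` from every TSS are left unassigned
    (not returned).  Distance ties are broken by gene id ascending.  When
    ``peak_fdr_max`` is given, peaks with ``score`` (FDR) above it are
    dropped first.
    """
    if peak_fdr_max is not None:
        peaks = [p for p in peaks if p.score is not None and p.score <= peak_fdr_max]
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append((tss_position(t), t.name))
    arrays = {}
    for chrom, items in by_chrom.items():
        items.sort()
        arrays[chrom] = (
            np.array([p for p, _ in items], dtype=float),
            [g for _, g in items],
        )
    rows = []
    missing_chroms = set()
    for p in peaks:
        if p.chrom not in arrays:
            missing_chroms.add(p.chrom)
            continue
        pos, genes = arrays[p.chrom]
        mid = p.midpoint
        i = int(np.searchsorted(pos, mid))
        cand = [j for j in (i - 1, i) if 0 <= j < len(pos)]
        dmin = min(abs(pos[j] - mid) for j in cand)
        if dmin > max_distance:
            continue
        # all TSS at the minimal distance (handles exact ties / duplicates)
        tied = [genes[j] for j in range(len(pos)) if abs(pos[j] - mid) == dmin]
        rows.append((p.name, min(tied), dmin))
    if missing_chroms:
        logger.warning(
            "peaks on chromosomes absent from the TSS file left unassigned: %s",
            sorted(missing_chroms),
        )
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"])


def classify_histone_dynamics(
    signal_pe: pd.DataFrame,
    signal_islet: pd.DataFrame,
    threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-peak, per-mark histone dynamics between the two stages.

    ``signal_pe`` and ``signal_islet`` are peak x mark tables covering the
    same peaks.  ``log2fc = log2((pe + pc) / (islet + pc))``; class is
    ``up_in_pe`` at >= threshold, ``down_in_pe`` at <= -threshold, else
    ``stable``.  Returns a long DataFrame (peak_id, mark, log2fc, class).
    """
    missing = signal_pe.index.symmetric_difference(signal_islet.index)
    if len(missing) > 0:
        raise ValueError(f"peaks missing in one stage: {list(missing[:5])}")
    rows = []
    for mark in signal_pe.columns:
        if mark not in signal_islet.columns:
            raise ValueError(f"mark {mark!r} missing in islet signal")
        pe = signal_pe[mark].astype(float)
        isl = signal_islet.loc[signal_pe.index, mark].astype(float)
        fc = np.log2((pe + pseudocount) / (isl + pseudocount))
        cls = np.where(fc >= threshold, "up_in_pe",
                       np.where(fc <= -threshold, "down_in_pe", "stable"))
        rows.append(pd.DataFrame({
            "peak_id": signal_pe.index, "mark": mark,
            "log2fc_pe_over_islet": fc.to_numpy(), "class": cls,
        }))
    return pd.concat(rows, ignore_index=True)


def dynamic_peaks(dynamics: pd.DataFrame, require_both: bool = False) -> set[str]:
    """Peaks whose marks are non-stable: any mark by default, all marks with
    ``require_both``."""
    nonstable = dynamics.assign(dyn=dynamics["class"] != "stable")
    agg = nonstable.groupby("peak_id")["dyn"].agg("all" if require_both else "any")
    return set(agg.index[agg])


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x over y with 0.5 credit for ties."""
    u = 0.0
    for xi in x:
        u += (xi > y).sum() + 0.5 * (xi == y).sum()
    return float(u)


def mann_whitney(
    x,
    y,
    alternative: str = "greater",
) -> tuple[float, float]:
    """One-sided Mann-Whitney test of ``x`` against ``y``.

    Exact p by full enumeration of all C(n+m, n) group assignments of the
    pooled observed values when both groups have <= 8 observations (correct
    under ties by construction); normal approximation with tie correction and
    continuity correction otherwise.  Returns (U of x, p).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    if alternative == "less":
        u_less, p = mann_whitney(y, x, "greater")
        return float(len(x) * len(y)) - u_less, p
    u_obs = _mann_whitney_u(x, y)
    if len(x) <= 8 and len(y) <= 8:
        pooled = np.concatenate([x, y])
        n = len(pooled)
        k = len(x)
        count = 0
        total = 0
        for idx in combinations(range(n), k):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            u = _mann_whitney_u(pooled[mask], pooled[~mask])
            count += u >= u_obs
            total += 1
        return u_obs, count / total
    res = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return u_obs, float(res.pvalue)


def validate_histone_expression_link(
    dynamics: pd.DataFrame,
    peak_gene: pd.DataFrame,
    expr_fc: pd.Series,
) -> dict:
    """Test that genes near PE-up histone peaks have higher PE/islet
    expression than genes near PE-down peaks.

    ``expr_fc`` maps gene -> log2 fold change (PE over islet).  One-sided
    Mann-Whitney with the up-class stochastically greater.
    """
    gene_of = dict(zip(peak_gene["peak_id"], peak_gene["gene_id"]))
    groups: dict[str, set[str]] = {"up_in_pe": set(), "down_in_pe": set()}
    for _, row in dynamics.iterrows():
        if row["class"] in groups and row["peak_id"] in gene_of:
            groups[row["class"]].add(gene_of[row["peak_id"]])
    for cls, genes in groups.items():
        genes &= set(expr_fc.index)
        groups[cls] = genes
        if not genes:
            raise ValueError(f"no genes in histone-dynamics class {cls!r}")
    up = expr_fc.loc[sorted(groups["up_in_pe"])].to_numpy()
    down = expr_fc.loc[sorted(groups["down_in_pe"])].to_numpy()
    u, p = mann_whitney(up, down, alternative="greater")
    return {
        "n_up_in_pe": len(up),
        "n_down_in_pe": len(down),
        "u_statistic": u,
        "p_up_greater": p,
    }


# --- motif scanning ---------------------------------------------------------

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


def _best_score(enc: np.ndarray, lo: np.ndarray) -> tuple[float, str]:
    """Best log-odds over all offsets and both strands.  ``lo`` is 4 x w."""
    w = lo.shape[1]
    if len(enc) < w:
        return -math.inf, "+"
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    fwd = lo[windows, np.arange(w)].sum(axis=1)
    rc = lo[:, ::-1][3 - windows, np.arange(w)].sum(axis=1)
    bf, br = float(fwd.max()), float(rc.max())
    return (bf, "+") if bf >= br else (br, "-")


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving exact dinucleotide counts.

    Builds the multigraph of observed dinucleotide transitions, draws a
    random last-out edge per vertex forming a tree into the final symbol
    (ensuring an Eulerian walk exists), and shuffles the remaining edges.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    verts = list(edges)
    for _ in range(1000):
        last_out = {
            v: (edges[v][rng.integers(len(edges[v]))] if v != last else None)
            for v in verts
        }
        ok = True
        # vertices other than `last` must reach `last` via last-out edges
        for v in verts:
            if v == last:
                continue
            seen = set()
            cur = v
            while cur != last and cur in last_out and last_out[cur] is not None:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = last_out[cur]
            if not ok or cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - fallback, should not trigger
        return seq
    out_lists = {}
    for v in verts:
        rest = list(edges[v])
        if v != last:
            rest.remove(last_out[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(last_out[v])
        out_lists[v] = rest
    result = [seq[0]]
    cur = seq[0]
    counters = {v: 0 for v in verts}
    for _ in range(len(seq) - 1):
        nxt = out_lists[cur][counters[cur]]
        counters[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)


def scan_motifs(
    pwms: dict[str, np.ndarray],
    peak_sequences: dict[str, str],
    background: np.ndarray | None = None,
    score_threshold_quantile: float = 0.99,
    seed: int | None = None,
) -> pd.DataFrame:
    """Log-odds motif scan of each PWM over each peak sequence.

    ``pwms`` maps TF id -> probability matrix with shape (4, width), rows in
    ACGT order, columns summing to 1.  The per-PWM hit threshold is the
    ``score_threshold_quantile`` quantile of best scores over one
    dinucleotide shuffle of every peak.  Returns hits only:
    DataFrame (peak_id, tf_id, score, strand).
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    los = {}
    for tf, pwm in pwms.items():
        pwm = np.asarray(pwm, dtype=float)
        if pwm.shape[0] != 4:
            raise ValueError(f"PWM {tf}: expected 4 rows (ACGT)")
        if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"PWM {tf}: columns must sum to 1")
        los[tf] = np.log2(np.maximum(pwm, 1e-9) / bg[:, None])

    peak_ids = sorted(peak_sequences)
    enc = {pid: _encode(peak_sequences[pid].upper()) for pid in peak_ids}
    shuf = {
        pid: _encode(dinucleotide_shuffle(peak_sequences[pid].upper(), rng))
        for pid in peak_ids
    }
    rows = []
    for tf in sorted(los):
        lo = los[tf]
        null = np.array([_best_score(shuf[pid], lo)[0] for pid in peak_ids])
        null = null[np.isfinite(null)]
        thr = float(np.quantile(null, score_threshold_quantile)) if len(null) else 0.0
        for pid in peak_ids:
            score, strand = _best_score(enc[pid], lo)
            if score >= thr and math.isfinite(score):
                rows.append((pid, tf, score, strand))
    return pd.DataFrame(rows, columns=["peak_id", "tf_id", "score", "strand"])


def assemble_graph(
    mirna_tf_map: dict[str, set[str]],
    motif_hits: pd.DataFrame,
    peak_gene: pd.DataFrame,
    dynamic_peak_ids: set[str],
    regulated_genes: set[str],
) -> nx.DiGraph:
    """Assemble the four-layer miRNA -> TF -> region -> gene graph.

    b-edges are kept only for motif hits in peaks that are assigned to a
    regulated gene and histone-dynamic; c-edges connect those peaks to their
    assigned gene.  Nodes not lying on at least one complete four-layer path
    are pruned, so every region node retains >= 1 b-edge and exactly one
    c-edge and every gene is reachable from a miRNA.
    """
    gene_of = dict(zip(peak_gene["peak_id"], peak_gene["gene_id"]))
    mapped_tfs = set().union(*mirna_tf_map.values()) if mirna_tf_map else set()
    # TF-layer genes cannot double as gene-layer nodes (strict 4-layer DAG)
    usable_peaks = {
        pid for pid, g in gene_of.items()
        if g in regulated_genes and g not in mapped_tfs and pid in dynamic_peak_ids
    }
    g = nx.DiGraph()
    for _, h in motif_hits.iterrows():
        if h["peak_id"] not in usable_peaks or h["tf_id"] not in mapped_tfs:
            continue
        g.add_node(h["tf_id"], node_type="tf")
        g.add_node(h["peak_id"], node_type="region")
        g.add_edge(h["tf_id"], h["peak_id"], layer="b", motif_score=float(h["score"]))
    for pid in [n for n, d in g.nodes(data=True) if d["node_type"] == "region"]:
        gene = gene_of[pid]
        g.add_node(gene, node_type="gene")
        g.add_edge(pid, gene, layer="c")
    for mirna, tfs in mirna_tf_map.items():
        for tf in tfs:
            if tf in g:
                g.add_node(mirna, node_type="mirna")
                g.add_edge(mirna, tf, layer="a")
    # prune nodes without a complete upstream chain (TFs with no a-edge)
    drop = [
        n for n, d in g.nodes(data=True)
        if d["node_type"] == "tf" and g.in_degree(n) == 0
    ]
    while drop:
        g.remove_nodes_from(drop)
        drop = [
            n for n, d in g.nodes(data=True)
            if (d["node_type"] in ("tf", "region", "gene") and g.in_degree(n) == 0)
            or (d["node_type"] in ("mirna", "tf", "region") and g.out_degree(n) == 0)
        ]
    counts = pd.Series(
        [d["node_type"] for _, d in g.nodes(data=True)], dtype=object
    ).value_counts().to_dict()
    if g.number_of_nodes() == 0:
        logger.warning("assembled regulatory graph is empty")
    else:
        logger.info("regulatory graph: nodes %s, edges %d", counts, g.number_of_edges())
    return g
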