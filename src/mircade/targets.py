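"""Seed-site scanning and direct-target calling.

Canonical miRNA target sites in a 3'UTR are defined by complementarity to
the miRNA seed (nucleotides 2-8 of the mature sequence):

* ``7mer-m8`` — UTR matches the reverse complement of seed nt 2-8;
* ``7mer-A1`` — UTR matches the reverse complement of nt 2-7 followed by an
  adenosine opposite miRNA position 1;
* ``8mer``    — both: reverse complement of nt 2-8 followed by that A.

An 8mer occurrence is reported once, as an 8mer, never additionally as the
7mers it contains.  Scanning is strandless (UTRs are provided sense strand)
and U/T-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


def _to_dna(seq: str, origin: str = "sequence") -> str:
    s = seq.upper().replace("U", "T")
    if set(s) - set("ACGT"):
        bad = sorted(set(s) - set("ACGT"))
        raise ValueError(f"{origin}: non-ACGT/U characters {bad}")
    return s


def reverse_complement(seq: str) -> str:
    return _to_dna(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA sequence (RNA, 5'->3')."""

    mirna_id: str
    mature_sequence: str

    def __post_init__(self) -> None:
        if len(self.mature_sequence) < 8:
            raise ValueError(f"{self.mirna_id}: mature sequence shorter than 8 nt")
        _to_dna(self.mature_sequence, origin=self.mirna_id)

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 (1-based) of the mature sequence, 7 nt."""
        return self.mature_sequence[1:8]

    @property
    def seed_match(self) -> str:
        """DNA reverse complement of the seed; the 7mer-m8 site sequence."""
        return reverse_complement(self.seed)


@dataclass(frozen=True)
class SeedSite:
    gene_id: str
    utr_position: int  # 0-based start of the site in the UTR
    site_type: str
    mirna_id: str


def scan_seed_sites(
    mirna: MiRNARecord,
    utrs: dict[str, str],
) -> list[SeedSite]:
    """All canonical seed sites of one miRNA across a set of UTRs.

    Overlapping occurrences are all reported.  Returned sites are sorted by
    (gene id, position).
    """
    m7 = mirna.seed_match  # reverse complement of seed nt 2-8, 7 nt
    m6a = m7[1:] + "A"     # reverse complement of nt 2-7 followed by A
    sites: list[SeedSite] = []
    for gene_id in sorted(utrs):
        seq = _to_dna(utrs[gene_id], origin=gene_id)
        # 7mer-m8 backbone; an A right after upgrades it to an 8mer
        start = seq.find(m7)
        while start != -1:
            if start + 7 < len(seq) and seq[start + 7] == "A":
                sites.append(SeedSite(gene_id, start, "8mer", mirna.mirna_id))
            else:
                sites.append(SeedSite(gene_id, start, "7mer-m8", mirna.mirna_id))
            start = seq.find(m7, start + 1)
        # 7mer-A1 unless it is the tail of an 8mer occurrence
        start = seq.find(m6a)
        while start != -1:
            if not (start > 0 and seq[start - 1] == m7[0]):
                sites.append(SeedSite(gene_id, start, "7mer-A1", mirna.mirna_id))
            start = seq.find(m6a, start + 1)
    sites.sort(key=lambda s: (s.gene_id, s.utr_position, s.site_type))
    return sites


@dataclass
class DirectTargetCall:
    gene_id: str
    mirna_ids: set[str]
    evidence: str  # seed_only | seed_and_clip | clip_only
    is_tf: bool = False
    site_types: dict[str, str] = field(default_factory=dict)  # mirna -> best type


_SITE_RANK = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 1}

MODES = ("seed_or_clip", "seed_and_clip", "seed_only")


def call_direct_targets(
    repressed: set[str],
    sites: list[SeedSite],
    clip_genes: set[str],
    mode: str = "seed_or_clip",
    tf_ids: set[str] | None = None,
) -> list[DirectTargetCall]:
    """Direct-target calls among repressed genes.

    ``clip_genes`` is the gene-level Argonaute-CLIP support set (a gene with
    any CLIP peak in its UTR counts as supported).  The default mode
    ``seed_or_clip`` calls a repressed gene when it has a canonical seed site
    and/or CLIP support; ``seed_and_clip`` requires both; ``seed_only``
    ignores CLIP for calling (it still annotates evidence).
    """
    if not repressed:
        raise ValueError("repressed gene set is empty")
    if mode not in MODES:
        raise ValueError(f"unknown mode: {mode!r}")
    tf_ids = tf_ids or set()
    by_gene: dict[str, list[SeedSite]] = {}
    for s in sites:
        by_gene.setdefault(s.gene_id, []).append(s)

    calls = []
    for gene in sorted(repressed):
        has_seed = gene in by_gene
        has_clip = gene in clip_genes
        if mode == "seed_or_clip":
            keep = has_seed or has_clip
        elif mode == "seed_and_clip":
            keep = has_seed and has_clip
        else:
            keep = has_seed
        if not keep:
            continue
        if has_seed and has_clip:
            evidence = "seed_and_clip"
        elif has_seed:
            evidence = "seed_only"
        else:
            evidence = "clip_only"
        best: dict[str, str] = {}
        for s in by_gene.get(gene, []):
            cur = best.get(s.mirna_id)
            if cur is None or _SITE_RANK[s.site_type] > _SITE_RANK[cur]:
                best[s.mirna_id] = s.site_type
        calls.append(
            DirectTargetCall(
                gene_id=gene,
                mirna_ids=set(best),
                evidence=evidence,
                is_tf=gene in tf_ids,
                site_types=best,
            )
        )
    n_by_ev = pd.Series([c.evidence for c in calls]).value_counts().to_dict()
    logger.info(
        "direct targets: %d/%d repressed genes (%.1f%%); evidence %s",
        len(calls), len(repressed), 100.0 * len(calls) / len(repressed), n_by_ev,
    )
    return calls


def clip_gene_support(
    clip_peaks,
    sites: list[SeedSite] | None = None,
    site_level: bool = False,
) -> set[str]:
    """Gene-level CLIP support set from peaks in UTR coordinates.

    ``clip_peaks`` are intervals whose ``chrom`` field holds the gene id and
    whose coordinates are 0-based half-open positions in that gene's UTR.
    With ``site_level=True`` (strict mode) a gene counts as supported only if
    a CLIP peak overlaps one of its predicted seed sites (site span of 8 nt).
    """
    if not site_level:
        return {p.chrom for p in clip_peaks}
    if sites is None:
        raise ValueError("site_level clip support needs the seed-site list")
    by_gene: dict[str, list[SeedSite]] = {}
    for s in sites:
        by_gene.setdefault(s.gene_id, []).append(s)
    supported = set()
    for p in clip_peaks:
        for s in by_gene.get(p.chrom, []):
            if p.start < s.utr_position + 8 and s.utr_position < p.end:
                supported.add(p.chrom)
                break
    return supported


def direct_target_summary(calls: list[DirectTargetCall], repressed: set[str]) -> dict:
    counts = {ev: 0 for ev in ("seed_only", "seed_and_clip", "clip_only")}
    for c in calls:
        counts[c.evidence] += 1
    return {
        "n_repressed": len(repressed),
        "n_direct": len(calls),
        "direct_pct_of_repressed": round(100.0 * len(calls) / len(repressed), 1)
        if repressed else 0.0,
        **counts,
    }


def build_mirna_tf_map(
    calls: list[DirectTargetCall],
    tf_ids: set[str],
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Per-miRNA sets of directly targeted TFs, with pairwise overlaps.

    Only seed-attributed support enters the map (gene-level CLIP does not
    identify which miRNA binds), so two miRNAs sharing seed nt 2-8 are
    guaranteed identical TF sets.
    """
    if not tf_ids:
        logger.warning("empty TF annotation: miRNA->TF map is empty")
        return {}, pd.DataFrame(columns=["mirna_a", "mirna_b", "overlap",
                                         "size_a", "size_b"])
    tf_map: dict[str, set[str]] = {}
    for c in calls:
        if c.gene_id not in tf_ids:
            continue
        for m in c.mirna_ids:
            tf_map.setdefault(m, set()).add(c.gene_id)
    rows = []
    for a, b in combinations(sorted(tf_map), 2):
        rows.append((a, b, len(tf_map[a] & tf_map[b]), len(tf_map[a]), len(tf_map[b])))
    overlaps = pd.DataFrame(
        rows, columns=["mirna_a", "mirna_b", "overlap", "size_a", "size_b"]
    )
    return tf_map, overlaps
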