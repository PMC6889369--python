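"""Permutation-test repression screens and gene-set enrichment.

The differential test statistic is the difference of group means of
log2(value + 1).  With n = 3 vs 3 samples there are only C(6,3) = 20 distinct
label permutations, so gene-wise label permutation alone cannot produce
p < 0.05; the default therefore pools the permutation null statistics across
genes (exchangeability of the per-gene noise), which gives fine-grained
p-values.  A label-only mode is available via ``pooled=False``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from mircade.config import InvalidConfigError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Non-negative expression values (RPKM scale), genes x samples, with a
    case/control label per sample."""

    values: pd.DataFrame
    condition_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0:
            raise ValueError("no features in expression matrix")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        missing = [s for s in self.values.columns if s not in self.condition_labels]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_of(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_labels[s] == label]


def compute_rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    mapped_totals: pd.Series,
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    ``value = count / (length_kb * mapped_millions)`` per gene and sample.
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing) > 0:
        raise ValueError(f"missing gene length for: {list(missing[:5])}")
    lengths = gene_lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    totals = mapped_totals.loc[counts.columns].astype(float)
    if (totals <= 0).any():
        raise ValueError("mapped totals must be > 0")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def _label_permutations(n_samples: int, n_case: int, n_perm: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Index sets (rows) of the case group under permuted labels.

    All distinct splits are used when there are at most ``n_perm`` of them
    (the observed split included); otherwise ``n_perm`` random splits are
    drawn with the given generator.
    """
    total = math.comb(n_samples, n_case)
    if total <= n_perm:
        return np.array(
            list(itertools.combinations(range(n_samples), n_case)), dtype=int
        )
    picks = np.empty((n_perm, n_case), dtype=int)
    for i in range(n_perm):
        picks[i] = rng.choice(n_samples, size=n_case, replace=False)
    return picks


def permutation_de(
    expr: ExpressionMatrix,
    n_perm: int = 10_000,
    side: str = "down",
    alpha: float = 0.05,
    seed: int | None = None,
    pooled: bool = True,
) -> pd.DataFrame:
    """Permutation-test differential expression (case over control).

    Returns a DataFrame indexed by gene id with columns ``log2fc`` (difference
    of group means of log2(value + 1)), ``p_value`` in (0, 1], ``direction``
    in {down, up, none} and ``significant`` (p < alpha on the queried side).
    """
    if n_perm < 1:
        raise InvalidConfigError("n_perm must be >= 1")
    if side not in ("down", "up", "both"):
        raise InvalidConfigError(f"unknown side: {side!r}")
    case = expr.samples_of("case")
    control = expr.samples_of("control")
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need >= 2 samples per condition")

    log = np.log2(expr.values[case + control].to_numpy(dtype=float) + 1.0)
    n_case = len(case)
    n_all = log.shape[1]
    observed = log[:, :n_case].mean(axis=1) - log[:, n_case:].mean(axis=1)

    rng = np.random.default_rng(seed)
    picks = _label_permutations(n_all, n_case, n_perm, rng)
    mask = np.zeros((picks.shape[0], n_all), dtype=bool)
    mask[np.arange(picks.shape[0])[:, None], picks] = True
    # per-permutation group means: genes x permutations
    case_means = log @ mask.T / n_case
    ctrl_means = log @ (~mask).T / (n_all - n_case)
    null = case_means - ctrl_means
    if pooled:
        logger.info(
            "pooled permutation null: %d genes x %d label splits = %d null stats",
            null.shape[0], null.shape[1], null.size,
        )

    if side == "both":
        obs_cmp = np.abs(observed)
        null_cmp = np.abs(null)
    elif side == "up":
        obs_cmp = observed
        null_cmp = null
    else:  # down: small (negative) statistics are extreme; flip sign
        obs_cmp = -observed
        null_cmp = -null

    if pooled:
        flat = np.sort(null_cmp.ravel())
        n_null = flat.size
        n_ge = n_null - np.searchsorted(flat, obs_cmp, side="left")
        p = (1.0 + n_ge) / (1.0 + n_null)
    else:
        n_ge = (null_cmp >= obs_cmp[:, None]).sum(axis=1)
        p = (1.0 + n_ge) / (1.0 + null_cmp.shape[1])

    direction = np.where(observed < 0, "down", np.where(observed > 0, "up", "none"))
    if side == "both":
        side_ok = direction != "none"
    else:
        side_ok = direction == side
    significant = (p < alpha) & side_ok
    return pd.DataFrame(
        {
            "log2fc": observed,
            "p_value": p,
            "direction": direction,
            "significant": significant,
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )


@dataclass
class SetOverlap:
    intersection: set
    size_a: int
    size_b: int
    size_intersection: int
    pct_of_a: float


def intersect_down_sets(set_a: set, set_b: set) -> SetOverlap:
    """Exact intersection of two gene sets with summary percentages.

    ``pct_of_a`` is 100 * |A ∩ B| / |A| rounded to one decimal (0.0 when A is
    empty).
    """
    a, b = set(set_a), set(set_b)
    inter = a & b
    pct = round(100.0 * len(inter) / len(a), 1) if a else 0.0
    return SetOverlap(inter, len(a), len(b), len(inter), pct)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def overrepresentation_test(
    query: set,
    universe: set,
    annotation_sets: dict[str, set],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each
    annotation set, BH-adjusted across sets, sorted by raw p ascending.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(query) <= set(universe):
        raise ValueError("query must be a subset of the universe")
    m_univ = len(universe)
    n_query = len(query)
    rows = []
    for name, members in annotation_sets.items():
        in_univ = set(members) & set(universe)
        overlap = len(in_univ & set(query))
        # P(X >= overlap), X ~ Hypergeom(M=m_univ, n=|set|, N=|query|)
        p = sps.hypergeom.sf(overlap - 1, m_univ, len(in_univ), n_query)
        rows.append((name, len(in_univ), overlap, float(p)))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_value"])
    df["q_value"] = _bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    df = df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    return df


def top_five(enrichment: pd.DataFrame) -> pd.DataFrame:
    """The five most enriched annotation sets (lowest raw p)."""
    return enrichment.head(5)


def gsea_running_sum(
    ranked_stats: pd.Series,
    gene_set: set,
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov-style running sum over a ranking.

    ``ranked_stats`` maps gene -> signed statistic and is sorted descending
    internally.  Hits increment proportionally to |statistic|^weight, misses
    decrement uniformly; the enrichment score is the extremum of the running
    sum (positive when the set concentrates at the top of the ranking).
    """
    s = ranked_stats.sort_values(ascending=False, kind="mergesort")
    genes = np.asarray(s.index)
    in_set = np.isin(genes, list(gene_set))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranking")
    if n_hit == len(genes):
        raise ValueError("gene set covers all ranked genes; ES undefined")
    w = np.abs(s.to_numpy(dtype=float)) ** weight
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit statistics are zero: fall back to uniform hits
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~in_set) / float(len(genes) - n_hit)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def gsea_enrichment(
    ranked_stats: pd.Series,
    gene_set: set,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = None,
) -> tuple[float, float]:
    """Enrichment score and permutation FDR for one gene set.

    The null permutes gene labels (random sets of the same size drawn from
    the ranking); the reported FDR is the fraction of null scores at least as
    extreme as |ES|.
    """
    if n_perm < 1:
        raise InvalidConfigError("n_perm must be >= 1")
    es, _ = gsea_running_sum(ranked_stats, gene_set, weight=weight)
    genes = list(ranked_stats.index)
    size = len(set(gene_set) & set(genes))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        fake = set(rng.choice(genes, size=size, replace=False))
        null[i], _ = gsea_running_sum(ranked_stats, fake, weight=weight)
    fdr = float((np.abs(null) >= abs(es)).mean())
    return es, fdr
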