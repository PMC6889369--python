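"""Stage-enrichment of miRNAs from small-RNA count matrices.

A miRNA is called induced in the endocrine stage when it passes both a raw
read-depth filter (mean raw reads in the endocrine stage above ``min_reads``)
and a fold-change filter on library-size-normalised (counts-per-million)
means.  The two filters reproduce the MA-plot selection of stage-induced
miRNAs; depth is judged on raw reads because it is a sequencing-coverage
statement, while the fold change is judged on CPM so that library-size
differences between stages do not masquerade as induction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mircade.config import InvalidConfigError


@dataclass
class CountMatrix:
    """Raw counts, features x samples, with a stage label per sample.

    ``counts`` is a DataFrame whose index holds feature ids and whose columns
    hold sample ids; ``stage_labels`` maps every sample id to its stage.
    """

    counts: pd.DataFrame
    stage_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0:
            raise ValueError("no features in count matrix")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup}")
        missing = [s for s in self.counts.columns if s not in self.stage_labels]
        if missing:
            raise ValueError(f"samples without stage label: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, stage: str) -> list[str]:
        return [s for s in self.counts.columns if self.stage_labels[s] == stage]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalisation (per-sample library size)."""
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = libsize.index[libsize <= 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    return counts.div(libsize, axis=1) * 1e6


def compute_ma_stats(
    counts: CountMatrix,
    stage_a: str,
    stage_b: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-miRNA MA statistics comparing stage ``b`` over stage ``a``.

    Group means are taken on the CPM scale; ``log2fc`` is
    ``log2((mean_b + pc) / (mean_a + pc))`` and ``raw_mean_b`` is the mean of
    raw reads in stage ``b`` (feeds the read-depth filter).

    Returns a DataFrame indexed by miRNA id with columns
    ``mean_a``, ``mean_b``, ``log2fc``, ``raw_mean_b``.
    """
    cols_a = counts.samples_of(stage_a)
    cols_b = counts.samples_of(stage_b)
    if not cols_a:
        raise ValueError(f"unknown stage label: {stage_a!r}")
    if not cols_b:
        raise ValueError(f"unknown stage label: {stage_b!r}")
    norm = cpm(counts.counts)
    mean_a = norm[cols_a].mean(axis=1)
    mean_b = norm[cols_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    raw_mean_b = counts.counts[cols_b].mean(axis=1)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "raw_mean_b": raw_mean_b,
        },
        index=counts.counts.index.rename("mirna_id"),
    )


def select_enriched(
    stats: pd.DataFrame,
    min_reads: float = 5000.0,
    min_fold: float = 2.3,
) -> list[str]:
    """miRNAs with raw stage-b mean reads > ``min_reads`` and linear fold
    change (stage b over stage a, on pseudocounted CPM means) > ``min_fold``,
    ordered by descending fold change.
    """
    if min_fold <= 0:
        raise InvalidConfigError("min_fold must be > 0")
    if stats.shape[0] == 0:
        raise ValueError("empty MA statistics")
    fold = np.power(2.0, stats["log2fc"])
    keep = (stats["raw_mean_b"] > min_reads) & (fold > min_fold)
    selected = stats.loc[keep].assign(_fold=fold[keep])
    selected = selected.sort_values("_fold", ascending=False, kind="mergesort")
    return list(selected.index)
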