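# mircade

Multi-layer miRNA → TF → chromatin-region → gene regulatory network
inference, with a planted-truth simulator for validating every stage.

## The problem

During pancreatic endocrine differentiation a handful of miRNAs (the Let-7
family, miR-200a, miR-375, …) rise sharply between the progenitor (PE) and
endocrine/islet stages. Their over-expression represses cell-cycle genes —
yet almost none of those cell-cycle transcripts carry miRNA seed sites. The
repression is indirect: the miRNAs directly silence a layer of transcription
factors, and the TFs' loss propagates to cell-cycle genes through their
binding regions in open chromatin. `mircade` implements the computational
side of that analysis for anyone with matched miRNA/mRNA/chromatin data:

1. **miRNA enrichment** — stage-induced miRNAs from small-RNA counts
   (raw-read depth > 5,000 in the endocrine stage AND CPM fold change > 2.3).
2. **Repression screens** — permutation-test differential expression
   (difference of group means of log2(x+1), null statistics pooled across
   genes so n = 3 vs 3 designs can reach p < 0.05), set intersections,
   hypergeometric over-representation with BH correction, and a
   GSEA-style weighted running-sum enrichment score.
3. **Direct-target calling** — canonical seed sites (8mer / 7mer-m8 /
   7mer-A1, matching the reverse complement of miRNA nt 2–8) and/or
   Argonaute-CLIP support among repressed genes; the per-miRNA TF map.
4. **Chromatin layer** — ATAC peaks (FDR ≤ 0.01) assigned to the closest
   TSS within 10 kb, H3K4me3/H3K27ac dynamics between stages (validated
   against expression with a one-sided Mann-Whitney test, exact for small
   groups), PWM log-odds motif scanning with dinucleotide-shuffled null
   thresholds.
5. **Scoring** — every miRNA→TF→region→gene path gets
   `S = a + b + c` (a: seed/CLIP strength, b: normalised motif score,
   c: `min(1, −log10 p / 4)` of the gene's differential test); a gene's
   combined score sums its per-miRNA best paths, so multi-miRNA genes
   outrank equally strong single-miRNA genes; the top-40 genes of a
   restriction set (e.g. cell cycle) form the reported subnetwork.

The simulator (`mircade.simulate`) generates all inputs with planted
cascades — negative-binomial small-RNA counts, log-normal expression
screens, sequences with embedded seed sites, motif-bearing peaks with
planted histone dynamics, CLIP peaks — so recovery and error rates are
measurable end to end.

## Worked example

```python
from mircade import SimulationConfig, AnalysisConfig, run_all

res = run_all(SimulationConfig(seed=4), AnalysisConfig(seed=4))
print(res.ranked.head(3).to_string(index=False))
print(f"cascade recovery: {res.cascade_recovery():.0%}")
```

prints (seed 4, default study conditions: 2,000 genes, 30 cascades,
4 enriched miRNAs, −1 log2 direct effect, 3 replicates per group):

```
gene_id  combined  n_mirnas                                            best_paths
  G0477 10.816741         4 miR-01>G1212>peak_c019:2.7042;miR-02>G1212>peak_c019:2.7042;miR-03>G0456>peak_c026:2.7042;miR-04>G0456>peak_c026:2.7042
  G0874 10.597749         4 miR-01>G1212>peak_c021:2.6494;miR-02>G1212>peak_c021:2.6494;miR-03>G0456>peak_c011:2.6494;miR-04>G0456>peak_c011:2.6494
  G0896 10.548992         4 miR-01>G1212>peak_c018:2.6372;miR-02>G1212>peak_c018:2.6372;miR-03>G0456>peak_c008:2.6372;miR-04>G0456>peak_c008:2.6372
cascade recovery: 100%
```

`combined` is the sum over the four miRNAs of each miRNA's best path score
(max 3 per path), `n_mirnas` the number of miRNAs with at least one complete
path to the gene, and `best_paths` the miRNA>TF>region routes behind the
score. All thirty planted cascade genes are recovered in the restricted
top-40 ranking.

The `examples/` directory holds one short script per capability
(simulation, enrichment, screens, target calling, network scoring, CLI);
each prints the numbers it computes and what they mean. The same pipeline
is scriptable from a shell:

```bash
mircade all --config examples/demo_config.yaml --out run/ --seed 7
```

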