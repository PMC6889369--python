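# Methods

## Model and rationale

`mircade` infers how a small set of stage-induced miRNAs indirectly
controls a downstream gene program. The causal model is a four-layer
directed acyclic graph: miRNAs repress transcription factors through
canonical 3'UTR seed sites; TFs act on genes through their binding regions
in open chromatin near transcription start sites; regions are credible only
when their histone marks move between the two stages. Every analysis stage
implements one filter or score of that model, and the simulator generates
data in which the model is true by construction, so that the pipeline's
sensitivity and error rates are measurable.

## Stage-by-stage procedure

**miRNA enrichment.** Counts are normalised to counts-per-million per
sample. A miRNA is called induced when (i) its mean *raw* read count in the
endocrine stage exceeds `min_reads` (default 5,000 — a sequencing-depth
statement, so judged on raw reads) and (ii) its linear CPM fold change
(endocrine over progenitor, pseudocount 1) exceeds `min_fold` (default
2.3). Whether the fold filter should use raw or normalised means, and which
pseudocount, are not universally standardised; both are exposed as
parameters and the defaults are documented here.

**Permutation differential expression.** Statistic: difference of group
means of log2(value + 1) (variance-stabilising on the RPKM scale). With
n = 3 vs 3 there are only C(6,3) = 20 label splits, so gene-wise label
permutation cannot reach p < 0.05; by default the null statistics of all
label splits are pooled across genes (assuming exchangeable per-gene
noise), giving p-values with resolution 1/(1 + genes × splits). The
conservative add-one estimator `p = (1 + #{null ≥ obs}) / (1 + N)` keeps
p in (0, 1]. A label-only mode (`pooled=False`) is available. When the
number of distinct splits exceeds `n_permutations`, splits are subsampled
with the stage seed (deterministic). One-sided down/up and two-sided modes
share the machinery; the pipeline's "regulated" set is the union of the
one-sided down and up calls at α, mirroring separately reported down- and
up-regulated sets.

**Set statistics.** Intersections report |A|, |B|, |A∩B| and the
percentage of A (one-decimal rounding). Over-representation uses the exact
hypergeometric upper tail with Benjamini–Hochberg adjustment across sets.
The GSEA-style statistic is the classic weighted Kolmogorov–Smirnov running
sum (hit increments ∝ |statistic|^w, w = 1 by default; miss decrements
uniform); significance comes from gene-label permutation, and the reported
FDR is the fraction of null scores at least as extreme as |ES|.

**Seed sites.** Site types follow the canonical definitions: 7mer-m8 =
reverse complement of miRNA nt 2–8; 7mer-A1 = reverse complement of nt 2–7
followed by an adenosine opposite position 1; 8mer = both. An 8mer
occurrence is reported once (never additionally as its contained 7mers);
overlapping occurrences are all reported; scanning is U/T-agnostic and
strandless (UTRs are sense strand). No 6mers and no context scoring: the
downstream use is a binary "predicted" flag plus a site-strength weight.
Direct-target calling defaults to seed-and/or-CLIP ("seed_or_clip"),
with stricter modes available; CLIP support is gene-level by default
(any peak in the UTR), site-level as a strict option. Only seed-attributed
evidence enters the miRNA→TF map, which guarantees that miRNAs sharing
seed nt 2–8 receive identical TF sets.

**Chromatin layer.** Peaks pass an FDR ≤ `peak_fdr_max` (default 0.01)
filter, then each peak is assigned to the single closest TSS by
|peak midpoint − TSS| within `tss_max_distance` (default 10 kb; midpoint
chosen because it is symmetric and summit information is not assumed),
ties broken by gene id. Histone dynamics per mark:
log2((PE + 1)/(islet + 1)) against a ±`histone_log2fc_threshold` (default
1.0) band; a peak is dynamic when either mark is non-stable (an AND mode
exists). The histone/expression coupling check compares the PE/islet
expression fold changes of genes near PE-up vs PE-down peaks with a
one-sided Mann-Whitney test — exact by full enumeration of the
C(n+m, n) group assignments when both groups have ≤ 8 observations
(correct under ties by construction), normal approximation with tie and
continuity correction otherwise. Motif scanning computes PWM log-odds
against the background at every offset on both strands; the per-PWM hit
threshold is the `motif_score_quantile` (default 0.99) quantile of best
scores over one Altschul–Erickson dinucleotide shuffle of every input
sequence, so thresholds adapt to motif information content without a
hand-set cutoff.

**Graph and scores.** b-edges (TF→region) exist only for motif hits in
peaks that are assigned to a regulated gene and histone-dynamic; c-edges
connect those peaks to their assigned genes; a-edges come from the
miRNA→TF map. TF-layer genes cannot double as gene-layer nodes (the four
layers are disjoint), and nodes not on a complete four-layer path are
pruned. Edge scores are made commensurable on [0, 1]:

* a = 0.5 · site strength (8mer 1, 7mer-m8 2/3, 7mer-A1 1/3; best site
  counts) + 0.5 · CLIP support (0/1);
* b = best motif log-odds, min–max normalised within each PWM (a PWM with
  a single hit maps to 1);
* c = min(1, −log10 p / 4) for the connected gene's differential test
  (the cap at p = 10⁻⁴ keeps c saturating rather than dominating).

The path score is the plain sum S = a + b + c, computed once and stored.
The combined gene score sums, over the distinct miRNAs reaching the gene,
each miRNA's maximum path score. This satisfies the qualitative
constraints the method requires — monotone in every edge score, strictly
increasing when a new miRNA gains a path, and ranking multi-miRNA genes
above equally strong single-miRNA genes — but the aggregation (sum of
per-miRNA maxima rather than, say, mean or sum over all paths) is a
package default, exposed at the API level. Ranking ties break
lexicographically by gene id for full determinism.

## The simulator

`plant_truth` draws TFs, stage-enriched miRNAs, `n_cascades`
miRNA→TF→gene triples (distinct miRNA–gene pairs; ~75% as many distinct
downstream genes as cascades, so some genes are reached by several
miRNAs), extra direct non-TF targets, and a "cell-cycle" restriction set
consisting of all cascade genes plus an equal number of decoys.
Generators then emit:

* **Sequences** — 22-nt miRNAs with pairwise-distinct seeds; 500-nt UTRs
  in which every planted direct pair gets one embedded 8mer site
  (reverse complement of seed nt 2–8 followed by A) and every other UTR is
  rejection-sampled (≤ 1,000 attempts) to carry no canonical site of any
  enriched miRNA; TSSs every `genome_length / n_genes` bp with alternating
  strands; near-indicator PWMs (0.97 consensus probability) per TF.
* **Small-RNA counts** — negative binomial with shared dispersion
  (default 0.1). Enriched miRNAs: endocrine mean 20,000 reads, fold 10
  over PE. Background miRNAs: one log-normal baseline (median 5,000,
  σ = 0.5 in ln units) in both stages. The repertoire default of 100
  miRNAs keeps the enriched mass a small fraction of the library, so CPM
  normalisation neither erases the planted fold nor shifts background
  miRNAs off the MA-plot diagonal — as in genome-wide small-RNA profiles.
* **Expression screens** — log-normal multiplicative noise (default
  σ = 0.15 log2 units, a typical replicate CV for sorted-cell RNA-seq)
  around per-gene log-normal baselines shared across conditions. Direct
  targets shift by the planted effect (default −1 log2) under the
  matching over-expression and poly-miR conditions; cascade genes
  additionally shift by `indirect_fraction` (default 0.5) of the direct
  effect under poly-miR, and by the full effect in the islet stage.
* **Chromatin and CLIP** — one peak per cascade within ±2 kb of the
  gene's TSS carrying the TF consensus and a planted PE-up histone gap of
  2 log2 units on both marks (cascade genes are islet-down); 500 decoy
  peaks within ±12 kb of random TSSs (some beyond the 10 kb assignment
  window, some failing the FDR filter, 10% dynamic in a random direction);
  CLIP peaks over a `clip_sensitivity` (default 0.3) fraction of planted
  seed sites plus a `clip_fpr` (default 0.05) per-gene false-positive
  rate. Because motif scanning needs sequence, the chromatin generator
  also emits a per-peak sequence FASTA rather than a full genome.

Every generator is bitwise deterministic for a fixed seed, with
independent sub-streams so adding one generator does not perturb another.

**What the simulator does not emulate:** raw reads and alignment, genome
sequence composition (peaks and UTRs are i.i.d. uniform DNA outside
planted elements), fragment-level ATAC structure, miRNA dosage
competition, and correlated biological replicate structure. Passing
recovery tests therefore demonstrates the pipeline's correctness under the
model's own assumptions — not performance on real libraries, where seed
sites cluster in AT-rich contexts and chromatin signal is far noisier.

## Default study conditions and problem sizes

The default `SimulationConfig` — 2,000 genes, 100 miRNAs (4 enriched),
8 TFs, 30 cascades, −1 log2 direct effect, 3 replicates per group,
dispersion 0.1 — is the condition under which the test suite measures
recovery: ≥ 95% enriched-miRNA recovery across 200 simulations, ≥ 80% of
planted cascade genes in the restricted top-40, type-I error within
[0.03, 0.07] at α = 0.05 over 2,000 null genes, and 100% multi-miRNA
outranking among equal-strength comparisons. Oracle-equivalence checks run
the seed scanner against exhaustive substring enumeration (1,000 UTRs × 20
miRNAs) and the path scorer against brute-force DFS enumeration (random
four-layer graphs, ≤ 500 paths).

## Numerical choices and degenerate inputs

Pseudocounts: 1 for CPM fold changes and histone ratios; log2(x + 1) for
expression. Permutation p-values use the add-one estimator. Min–max motif
normalisation maps a degenerate (single-value) score range to 1.0.
Sorting is mergesort throughout where ties must be stable; all ranking
ties break by id. Empty graphs, empty restriction overlaps and zero
cascades are allowed and produce empty (warned) results rather than
errors; invalid configurations (dispersion ≤ 0, UTR < 8 nt, genome too
small for unambiguous peak placement, n_cascades > n_genes) fail fast
with `InvalidConfigError`.

## Known limitations

The combined-score aggregation and the three edge-score normalisations
are commensurability conventions, not fitted quantities; rankings are
robust to monotone rescalings of a single layer only insofar as layers
remain comparable. CLIP support is not miRNA-resolved, so clip-only calls
carry no miRNA attribution and do not enter the miRNA→TF map. The pooled
permutation null assumes exchangeable per-gene noise; genes with planted
effects contaminate the pool slightly (conservatively). TSS assignment is
midpoint-based and ignores looping-based regulation entirely.
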