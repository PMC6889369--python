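"""Assemble the four-layer regulatory graph and rank genes.

Regions enter the graph when they pass the peak FDR filter, lie within
10 kb of the closest TSS of a differentially regulated gene, are
histone-dynamic between stages, and carry a miRNA-targeted TF's motif.
Each miRNA -> TF -> region -> gene path scores s = a + b + c; per-gene
combined scores sum the per-miRNA best paths.
"""

from mircade import AnalysisConfig, SimulationConfig, run_all

res = run_all(SimulationConfig(seed=4), AnalysisConfig(seed=4))

g = res.graph
by_type = {}
for _, d in g.nodes(data=True):
    by_type[d["node_type"]] = by_type.get(d["node_type"], 0) + 1
print(f"graph nodes by layer: {by_type}; edges: {g.number_of_edges()}")
print(f"complete miRNA->TF->region->gene paths: {len(res.paths)}")

if res.histone_link:
    p = res.histone_link["p_up_greater"]
    print(f"histone-dynamics vs expression coupling (one-sided Mann-Whitney): "
          f"p = {p:.2e}")

print("\ntop 10 of the cell-cycle-restricted ranking:")
print(res.ranked.head(10).to_string(index=False))
rec = res.cascade_recovery()
print(f"\nplanted cascade genes recovered in the top-{len(res.ranked)}: "
      f"{rec:.0%}")
# 'combined' sums, over the miRNAs reaching a gene, each miRNA's best path
# score — genes under multi-miRNA control therefore outrank genes reached
# equally strongly by a single miRNA.
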