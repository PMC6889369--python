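# Desk-scale demo configuration for `mircade all`.
simulation:
  n_genes: 300
  n_mirnas: 30
  n_enriched: 4
  n_tfs: 6
  n_cascades: 10
  genome_length: 9000000
analysis:
  n_permutations: 5000
  top_k: 20
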