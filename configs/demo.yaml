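# Bundled demo: a scaled-down structured panel through the full pipeline.
simulate:
  lines_per_pool: [40, 15]
  n_ril: 5
  loci_per_chrom: [14, 14, 14, 14, 14, 14, 14, 14, 14, 14, 14]
  missing_rate: 0.06
  het_error_rate: 0.01
  seed: 42
window_range: [5, 20]
k_pcs: 4
fdr: 0.05
scope: all_pairs
decay_threshold: 0.1
interchrom_tiers: [0.7, 0.8, 0.9]
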