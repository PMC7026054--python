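# Demo pipeline configuration for `eqtlscores run-all --config examples/config.yaml --out run/`
simulation:
  n_ref: 2000          # reference-panel individuals for LD estimation
  n_subjects: 1500     # imaging-cohort subjects
  n_blocks: 8
  snps_per_block: 16
  rho: 0.5             # within-block latent LD
  maf_range: [0.05, 0.5]
  n_genes_study_a: 6
  n_genes_study_b: 6
  n_overlap_genes: 2   # genes scored by both discovery studies
  n_causal_genes: 1
  effect_size: 0.15    # planted standardized effect (demo-sized for visibility)
  hemi_corr: 0.75
  seed: 42
p_threshold: 1.0e-5
fdr_q: 0.05
quadratic: true
overlap_comparison: true
mixed_bilateral: true
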