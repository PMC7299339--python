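# Full pipeline configuration for `sproutnet run --config examples/run.yaml`
# (or sproutnet.run_pipeline in Python). Exactly one of `synthetic:` or
# `inputs:` selects the data source.
synthetic:
  seed: 11            # generator seed; omit to derive one from the master seed
de:
  min_raw: 5          # strict mean-raw-count expression cutoff
  lfc_threshold: 0.5
  fdr_cutoff: 0.05
correlation:
  n_perm: 1000        # sample-randomization permutations for the null
gsea:
  n_perm: 1000
  association_matrix: true
network:
  p_threshold: 0.05
  conservation_mode: conserved_only
  p_column: p_analytic
  powerlaw_bootstrap: 200
cohort: {}            # enable the synthetic cohort stage with defaults
ddct: {}              # enable the synthetic qPCR-card stage with defaults
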