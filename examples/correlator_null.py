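"""Compare the observed miRNA-gene correlator distribution with its
permutation null and test the conserved-prediction stratum for the
negative-correlation enrichment that repression leaves behind."""

import sproutnet as sn

mir, gene, predictions, _, _ = sn.generate_experiment(sn.SyntheticConfig(seed=1))
mir_l = sn.normalize_counts(sn.filter_expressed(mir)).to_log2()
gene_l = sn.normalize_counts(sn.filter_expressed(gene)).to_log2()

correlations = sn.pairwise_correlation(mir_l, gene_l)
null = sn.permutation_null(mir_l, gene_l, n_perm=1000, seed=7)
correlations = sn.attach_empirical_p(correlations, null)

print(f"null: {null.n_pooled} pooled draws from {null.n_permutations} "
      f"sample shuffles, mean r = {null.mean:+.5f}")
for stratum in ("conserved", "nonconserved"):
    rec = sn.stratified_distribution_test(correlations, predictions, stratum)
    print(f"{stratum:>13}: n={rec['n_stratum']:4d}  mean r = "
          f"{rec['mean_r_stratum']:+.3f}  one-sided KS p = "
          f"{rec['p_negative_shift']:.2e}")
print("The conserved stratum (which carries the planted repressions) is "
      "shifted toward negative correlators; the decoy-only non-conserved "
      "stratum matches the background.")
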