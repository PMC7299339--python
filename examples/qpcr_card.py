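"""Process a TaqMan-card-style Ct table with the comparative-Ct method and
recover the assays whose expression was planted to change."""

import sproutnet as sn

shifted = [f"miR-{i+1:03d}" for i in range(5)]
table, condition, truth = sn.generate_ct_card(
    n_mirna=30, shifted_ids=shifted, shift_ddct=3.0, seed=8, noise_sd=0.3)

result = sn.ddct_analysis(table, condition,
                          reference_assays=truth.reference_assays)
altered = result[result["passes_threshold"]]
print(f"{len(altered)} of {len(result)} assays pass |ddCt| > 2:")
for assay in result.attrs["cluster_order"]:
    row = result.loc[assay]
    print(f"  {assay}: ddCt = {row['ddct']:+.2f}, Rq = {row['rq']:.3f}")
print(f"planted shifts recovered: "
      f"{sorted(set(altered.index) & set(shifted)) == sorted(shifted)}")
print("ddCt > 0 means lower expression in the treated condition "
      "(Rq = 2^-ddCt is the fold change); rows are ordered by hierarchical "
      "clustering of -ddCt.")
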