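"""Aggregate per-CpG calls into a gene x sample methylation matrix.

A CpG site only counts if it reaches >= 5X coverage in every sample of the
analysis set, and a gene only gets a value if it holds >= 5 such CpGs —
otherwise the entry is missing (NA), not zero. The gene value is the
unweighted mean of its qualifying per-CpG methylation ratios.
"""

import methvar as mv

ds = mv.simulate_dataset(n_genes=40, samples_per_group=3, n_locations=2, seed=2)
tables = ds.site_tables()

qualified = mv.qualifying_cpg_sites(tables, min_coverage=5)
total = (ds.sites["context"] == "CpG").sum()
print(f"{len(qualified)} of {total} CpG sites covered >= 5X in all {len(tables)} samples")

matrix = mv.build_matrix(ds.samples, ds.genes, tables)
print(f"matrix: {matrix.values.shape[0]} genes x {matrix.values.shape[1]} samples, "
      f"{int(matrix.values.isna().sum().sum())} missing entries")
print(f"qualifying CpGs per gene: median {int(matrix.n_cpgs_used.median())}, "
      f"min {int(matrix.n_cpgs_used.min())}")
print("\nfirst genes x first samples (methylation ratios):")
print(matrix.values.iloc[:4, :4].round(3).to_string())
print("\nvalues near 0/1 are consistently (un)methylated genes; intermediate")
print("values mark the variably methylated fraction the analysis targets")
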