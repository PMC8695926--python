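"""Tissue- and location-specific differential methylation with recovery scoring.

Runs the two stratified contrasts on a simulated dataset with planted
effects: a Wilcoxon rank-sum test (hepatopancreas vs. abdominal muscle
within one location) and a Kruskal-Wallis test (across locations within
one tissue), both followed by Benjamini-Hochberg correction. Because the
simulation carries ground truth, the called gene lists can be scored as
precision/recall. Also shows a per-CpG profile of one hit and the
run-based DMR scan that localizes the signal within the gene.
"""

import methvar as mv

ds = mv.simulate_dataset(seed=4)  # default study conditions: 2 tissues x 4 locations x 12
tables = ds.site_tables()

# location contrast within hepatopancreas
hep = ds.samples[ds.samples["tissue"] == "hepatopancreas"]
matrix = mv.build_matrix(hep, ds.genes, {s: tables[s] for s in hep["sample_id"]})
labels = hep.set_index("sample_id")["location"]
res, skipped = mv.differential_genes(matrix, labels, test="kruskal_wallis", alpha=0.05)
sig = list(res.loc[res["significant"], "gene_id"])
precision, recall = mv.recovery_scores(sig, ds.truth, "location")
print(f"location contrast (Kruskal-Wallis, {len(hep)} hepatopancreas samples):")
print(f"  {len(sig)} significant genes at q < 0.05; "
      f"precision {precision:.2f}, recall {recall:.2f} vs. planted truth")

# tissue contrast within the first location
loc = ds.samples["location"].iloc[0]
stratum = ds.samples[ds.samples["location"] == loc]
t_matrix = mv.build_matrix(stratum, ds.genes, {s: tables[s] for s in stratum["sample_id"]})
t_res, _ = mv.differential_genes(
    t_matrix, stratum.set_index("sample_id")["tissue"], test="wilcoxon", alpha=0.05
)
t_sig = list(t_res.loc[t_res["significant"], "gene_id"])
t_precision, t_recall = mv.recovery_scores(t_sig, ds.truth, "tissue")
print(f"tissue contrast (Wilcoxon, {len(stratum)} samples from {loc}):")
print(f"  {len(t_sig)} significant genes; precision {t_precision:.2f}, recall {t_recall:.2f}")

inter, only_a, only_b = mv.overlap_genes(sig, t_sig)
print(f"overlap between the two contrasts: {len(inter)} genes "
      f"(location-only {only_a}, tissue-only {only_b}) — planted effects are disjoint\n")

# localize the effect within one significant location gene
gene_id = sig[0]
gene = mv.GeneModel(**ds.genes.set_index("gene_id").loc[gene_id].to_dict() | {"gene_id": gene_id})
track = mv.per_cpg_profile(gene, {s: tables[s] for s in hep["sample_id"]}, labels)
dmrs = mv.scan_dmrs(track, scaffold=gene.scaffold, min_sites=5, min_delta=0.1)
truth_row = ds.truth.genes.set_index("gene_id").loc[gene_id]
print(f"per-CpG profile of {gene_id}: {len(track)} CpGs x {track.shape[1]} location means")
for d in dmrs:
    print(f"  DMR {d.start}-{d.end}: {d.n_cpgs} CpGs, "
          f"mean group difference {d.mean_abs_difference:.2f}")
print(f"  (planted window spans CpG indices {int(truth_row.dmr_start_idx)}-"
      f"{int(truth_row.dmr_end_idx)} of this gene: the signal is localized,")
print("   not gene-wide, which is why per-CpG views outperform gene averages)")
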