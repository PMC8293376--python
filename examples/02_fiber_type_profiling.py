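"""Fiber-type characterization: MYH calls, marker table, clustering, PCA.

Each MYH-like isoform should be called in its characteristic fiber type
(MYH7->I, MYH2->IIa, MYH4->IIb, MYH1->IIx); slow markers fall and fast
markers rise along the I -> IIa -> IIx -> IIb ordering; and the
filter/impute/cluster chain groups proteins by expression profile.
"""

import numpy as np

import fibertype as ft

matrix, truth = ft.generate(ft.SimConfig(seed=2, n_samples_per_type=6,
                                         n_background_proteins=60))

# 1. MYH isoform fiber calling from proteotypic peptide sums
isoform_map = {f"{n}_SYN": n for n in ("MYH7", "MYH2", "MYH4", "MYH1")}
call = ft.myh_fiber_call(matrix, isoform_map)
print("MYH calls:", {iso: call.call(iso) for iso in sorted(call.called_type)})

# 2. Slow/fast marker percentages per fiber type
quant = ft.quantify(matrix)
table = ft.marker_table(quant, {"SLOW1_SYN": "slow", "FAST1_SYN": "fast"})
print("\nmarker percentages by fiber type:")
print(table.round(3))

# 3. Filter (50% valid values) -> downshifted-normal imputation -> cluster
log_protein = np.log2(quant.ibaq)
filtered = ft.filter_valid(log_protein, 0.5)
imputed = ft.impute_downshift(filtered, width=0.3, downshift=1.8, seed=2)
result = ft.cluster_profiles(imputed, matrix.sample_labels, n_final=4, seed=2)
print("\ncluster sizes:", result.sizes.to_dict())
print("cluster median Z-score profiles:")
print(result.profiles.round(2))

# 4. Annotation percentages with respect to cluster size
categories = {p: c for p, c in truth.true_protein_class.items()}
ann = ft.annotate_percentages(result, categories)
print("\nannotation percentages (% of cluster size):")
print(ann.percent)

# 5. PCA: sample scores and the proteins driving the separation
scores, loadings, explained = ft.pca_loadings(imputed)
print("\nexplained variance PC1/PC2:", explained.round(2))
print("top 3 separating proteins:", list(loadings.index[:3]))
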