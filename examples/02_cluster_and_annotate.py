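"""QC, cluster and annotate one simulated cohort.

Walks the preprocessing path: detected-gene / mitochondrial QC, median-depth
log1p normalization with trend-standardized HVG selection, PCA with the elbow
rule, SNN + Louvain over a resolution grid, silhouette-based model selection,
and specificity-weighted marker annotation.
"""

import pandas as pd

from sccompare import preprocess, simdata

cfg = simdata.SimConfig(
    n_genes=2000, n_cell_types=3, cells_per_donor=300, donors_per_condition=1,
    n_markers_per_type=10, marker_fold=8.0, seed=2,
)
bundle, truth = simdata.generate_cohort(cfg, "A")

filtered = preprocess.qc_filter(bundle)  # 200-10000 genes, <=5% mito
norm = preprocess.normalize_and_select_hvg(filtered, n_hvg=1000)
k, scores = preprocess.select_pcs_elbow(norm.hvg_matrix, max_pcs=17)
print(f"kept {filtered.n_cells}/{bundle.n_cells} cells, {k} PCs")

best, solutions = preprocess.cluster_with_silhouette(scores, seed=0)
for s in solutions:
    marker = " <- selected" if s.resolution == best.resolution else ""
    print(f"resolution {s.resolution:.1f}: {s.n_clusters} clusters, "
          f"mean silhouette {s.mean_silhouette:.3f}{marker}")

markers = pd.DataFrame(
    [{"cell_type": ct, "gene": g} for ct, gs in truth.markers.items() for g in gs]
)
ann = preprocess.annotate_clusters(norm.matrix, norm.gene_ids, best.labels, markers)
print("\ncluster annotations (marker z-score sums):")
print(ann.assignments.to_string(index=False))

# Fine labels can be merged into coarse classes, the way layer-resolved
# excitatory neuron subclusters collapse into one "Excitatory neuron" label:
merged = preprocess.merge_labels(ann, {"type_1": "type_1/2", "type_2": "type_1/2"})
print("\nafter merging type_1 and type_2:",
      sorted({str(lbl) for lbl in merged.cell_labels}))
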