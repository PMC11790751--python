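import numpy as np
import pandas as pd
import pytest

from sccompare import preprocess, simdata
from sccompare.preprocess import (
    AnnotatedClusters,
    EmptyResultError,
    QCParams,
    annotate_clusters,
    cluster_with_silhouette,
    merge_labels,
    normalize_and_select_hvg,
    qc_filter,
    select_pcs_elbow,
)

from conftest import make_bundle


# ---------------------------------------------------------------- QC filter


def test_qc_thresholds_and_boundaries():
    """Four cells around the QC rules: 150 detected genes (removed), exactly
    200 detected (retained), 6.1% mitochondrial (removed), exactly 5.0%
    mitochondrial (retained).  Gene 0 (MT-ND1) is the mitochondrial gene."""
    counts = np.zeros((300, 4), dtype=int)
    counts[:150, 0] = 1  # cell 0: 150 detected -> below min_genes
    counts[:200, 1] = 1  # cell 1: exactly 200 detected (mito 1/200 = 0.5%)
    counts[0, 2] = 13  # cell 2: 13 / (13 + 200) ~ 6.1% mito -> removed
    counts[1:201, 2] = 1
    counts[0, 3] = 11  # cell 3: 11 / (11 + 209) = 5.0% mito exactly, 210 genes
    counts[1:210, 3] = 1
    symbols = ["MT-ND1"] + [f"g{i}" for i in range(1, 300)]
    bundle = make_bundle(counts, symbols=symbols, conditions=["disease"] * 4)
    kept = qc_filter(bundle, QCParams())
    assert kept.cells["cell_id"].tolist() == ["c1", "c3"]


def test_qc_all_cells_removed_raises():
    counts = np.ones((300, 3), dtype=int)  # every cell detects 300 genes
    bundle = make_bundle(counts, conditions=["disease"] * 3)
    with pytest.raises(EmptyResultError):
        qc_filter(bundle, QCParams(min_genes_per_cell=100, max_genes_per_cell=299))


def test_qc_identity_and_idempotence():
    rng = np.random.default_rng(0)
    counts = rng.poisson(2.0, size=(500, 20))
    bundle = make_bundle(counts, conditions=["disease"] * 20)
    params = QCParams(min_genes_per_cell=10, max_genes_per_cell=500)
    once = qc_filter(bundle, params)
    assert once.n_cells == bundle.n_cells  # all cells within bounds: identity
    twice = qc_filter(once, params)
    assert (twice.counts != once.counts).nnz == 0


def test_qc_param_validation():
    with pytest.raises(ValueError):
        QCParams(min_genes_per_cell=500, max_genes_per_cell=200)
    with pytest.raises(ValueError):
        QCParams(max_mito_fraction=1.5)


# ------------------------------------------------- normalization and HVGs


def test_constant_gene_never_outranks_variable_gene():
    rng = np.random.default_rng(1)
    counts = rng.poisson(3.0, size=(50, 40))
    counts[7] = 2  # constant across cells
    bundle = make_bundle(counts, conditions=["disease"] * 40)
    norm = normalize_and_select_hvg(bundle, n_hvg=49)
    assert 7 not in set(norm.hvg_indices)


def test_hvg_saturation_returns_all_genes():
    rng = np.random.default_rng(2)
    bundle = make_bundle(rng.poisson(2.0, size=(30, 25)) + 1,
                         conditions=["disease"] * 25)
    norm = normalize_and_select_hvg(bundle, n_hvg=10_000)
    assert len(norm.hvg_indices) == 30


def test_hvg_statistic_invariant_to_cell_permutation():
    rng = np.random.default_rng(3)
    counts = rng.poisson(2.0, size=(40, 30)) + 1
    counts[5] = counts[9][::-1]  # gene 5 = permutation of gene 9's values
    # equalize depth influence: use equal-depth cells
    counts[-1] = counts[-1] * 0 + (counts.sum(axis=0).max() - counts[:-1].sum(axis=0))
    bundle = make_bundle(counts, conditions=["disease"] * 30)
    norm = normalize_and_select_hvg(bundle, n_hvg=40)
    rank = {g: i for i, g in enumerate(norm.hvg_indices)}
    # identical multisets of normalized values -> identical variance statistic
    assert abs(rank[5] - rank[9]) == 1  # adjacent in the ranking (tied)


def test_zero_depth_cell_rejected():
    counts = np.ones((10, 3), dtype=int)
    counts[:, 1] = 0
    bundle = make_bundle(counts, conditions=["disease"] * 3)
    with pytest.raises(ValueError, match="zero total"):
        normalize_and_select_hvg(bundle)


# ----------------------------------------------------------------- PCA elbow


def test_elbow_on_low_rank_data():
    rng = np.random.default_rng(4)
    basis = rng.normal(size=(3, 80))
    load = rng.normal(size=(200, 3)) * np.array([5.0, 4.0, 3.0])
    X = (load @ basis + rng.normal(scale=1e-3, size=(200, 80))).T  # genes x cells
    k, scores = select_pcs_elbow(X, max_pcs=17)
    assert k <= 4
    assert scores.shape == (200, k)


def test_elbow_falls_back_to_max_pcs_on_isotropic_data():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(60, 150))  # genes x cells, no structure
    k, _ = select_pcs_elbow(X, max_pcs=17)
    assert k == 17


def test_fixed_pc_override():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(60, 150))
    k, scores = select_pcs_elbow(X, max_pcs=30, n_pcs=17)
    assert k == 17 and scores.shape[1] == 17


def test_elbow_rejects_degenerate_input():
    with pytest.raises(ValueError):
        select_pcs_elbow(np.ones((5, 1)))
    with pytest.raises(ValueError):
        select_pcs_elbow(np.ones((3, 8)))  # constant -> rank 0


# ----------------------------------------------------------------- clustering


def _blobs(n_per=60, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [sep, 0], [0, sep]], dtype=float)
    pts = np.vstack([c + rng.normal(size=(n_per, 2)) for c in centers])
    labels = np.repeat([0, 1, 2], n_per)
    return pts, labels


def test_three_blobs_recovered_with_high_silhouette():
    pts, true = _blobs()
    best, all_solutions = cluster_with_silhouette(pts, knn=15)
    assert best.n_clusters == 3
    assert best.mean_silhouette > 0.8
    # the selected solution dominates the grid
    assert all(best.mean_silhouette >= s.mean_silhouette for s in all_solutions)


def test_identical_coordinates_exercise_singleton_sentinel():
    pts = np.zeros((40, 3))
    best, solutions = cluster_with_silhouette(pts, knn=5)
    assert all(s.n_clusters == 1 for s in solutions)
    assert best.mean_silhouette == -1.0


def test_too_few_cells_rejected():
    with pytest.raises(ValueError, match="knn"):
        cluster_with_silhouette(np.zeros((5, 2)), knn=20)


# ----------------------------------------------------------------- annotation


def _marker_table():
    return pd.DataFrame(
        {
            "cell_type": ["astro", "astro", "neuron", "neuron", "pan"],
            "gene": ["g0", "g1", "g2", "g3", "g0"],
        }
    ).replace({"pan": "microglia"})


def test_cluster_overexpressing_astro_markers_labeled_astro():
    rng = np.random.default_rng(7)
    X = rng.poisson(1.0, size=(6, 90)).astype(float)
    labels = np.repeat([0, 1, 2], 30)
    X[0:2, labels == 0] += 20  # astro markers up in cluster 0
    X[2:4, labels == 1] += 20  # neuron markers up in cluster 1
    gene_ids = np.array([f"g{i}" for i in range(6)])
    markers = pd.DataFrame(
        {"cell_type": ["astro", "astro", "neuron", "neuron"],
         "gene": ["g0", "g1", "g2", "g3"]}
    )
    ann = annotate_clusters(X, gene_ids, labels, markers)
    lut = dict(zip(ann.assignments["cluster"], ann.assignments["cell_type"]))
    assert lut[0] == "astro" and lut[1] == "neuron"
    assert lut[2] == "unknown"  # no marker elevated -> below confidence floor


def test_promiscuous_marker_downweighted():
    """A marker listed for every type carries weight 1/n_types and cannot
    override a specific marker."""
    rng = np.random.default_rng(8)
    X = rng.poisson(1.0, size=(3, 60)).astype(float)
    labels = np.repeat([0, 1], 30)
    X[0, labels == 0] += 30  # shared marker, up in cluster 0
    X[1, labels == 0] += 30  # specific astro marker, up in cluster 0
    X[2, labels == 1] += 30  # specific neuron marker, up in cluster 1
    gene_ids = np.array(["shared", "astro_m", "neuron_m"])
    markers = pd.DataFrame(
        {"cell_type": ["astro", "neuron", "astro", "neuron"],
         "gene": ["shared", "shared", "astro_m", "neuron_m"]}
    )
    ann = annotate_clusters(X, gene_ids, labels, markers, confidence_factor=0.01)
    lut = dict(zip(ann.assignments["cluster"], ann.assignments["cell_type"]))
    assert lut[0] == "astro" and lut[1] == "neuron"


def test_annotation_invariant_to_cluster_relabeling():
    rng = np.random.default_rng(9)
    X = rng.poisson(1.0, size=(4, 80)).astype(float)
    labels = np.repeat([0, 1], 40)
    X[0, labels == 0] += 15
    X[1, labels == 1] += 15
    gene_ids = np.array(["m0", "m1", "x", "y"])
    markers = pd.DataFrame({"cell_type": ["t0", "t1"], "gene": ["m0", "m1"]})
    a1 = annotate_clusters(X, gene_ids, labels, markers, confidence_factor=0.1)
    a2 = annotate_clusters(X, gene_ids, 1 - labels, markers, confidence_factor=0.1)
    assert list(a1.cell_labels) == list(a2.cell_labels)
    assert set(a1.cell_labels) == {"t0", "t1"}


def test_empty_marker_table_rejected():
    with pytest.raises(ValueError, match="empty"):
        annotate_clusters(np.ones((2, 4)), np.array(["a", "b"]),
                          np.zeros(4, dtype=int), pd.DataFrame())


def test_absent_markers_warn_and_are_ignored():
    rng = np.random.default_rng(10)
    X = rng.poisson(1.0, size=(2, 40)).astype(float)
    labels = np.repeat([0, 1], 20)
    X[0, labels == 0] += 10
    markers = pd.DataFrame({"cell_type": ["t0", "t0"], "gene": ["g0", "nope"]})
    with pytest.warns(UserWarning, match="absent"):
        annotate_clusters(X, np.array(["g0", "g1"]), labels, markers)


# ----------------------------------------------------------------- merging


def _annotated(labels):
    per_cluster = pd.DataFrame(
        {"cluster": range(len(labels)), "cell_type": labels,
         "score": 1.0, "confident": True}
    )
    return AnnotatedClusters(assignments=per_cluster,
                             cell_labels=np.array(labels))


def test_merge_fine_neuron_subtypes():
    ann = _annotated(["Exc L2", "Exc L5", "astro"])
    merged = merge_labels(ann, {"Exc L2": "Excitatory neuron",
                                "Exc L5": "Excitatory neuron"})
    assert list(merged.assignments["cell_type"]) == [
        "Excitatory neuron", "Excitatory neuron", "astro"]
    assert list(merged.assignments["cluster"]) == [0, 1, 2]  # ids preserved


def test_merge_empty_map_is_identity_and_counts_add():
    ann = _annotated(["a", "b", "b"])
    assert list(merge_labels(ann, {}).cell_labels) == ["a", "b", "b"]
    merged = merge_labels(ann, {"a": "b"})
    assert (merged.cell_labels == "b").sum() == 3
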