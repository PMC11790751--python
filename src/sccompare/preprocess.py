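"""QC, normalization, dimensionality reduction, clustering and annotation.

The stages mirror a standard droplet scRNA-seq workflow: cells are filtered on
detected-gene counts (200-10000) and mitochondrial fraction (<=5%), counts are
depth-normalized to the median cell depth and log1p-transformed, the top 3000
trend-standardized highly variable genes feed a PCA whose retained dimension is
picked by an elbow rule (bounded at 17 by default), a shared-nearest-neighbor
graph is clustered with Louvain over a resolution grid, and the grid solution
with the best mean silhouette width wins.  Clusters are labeled by a
specificity-weighted marker z-score; fine neuron subtypes can be merged into
coarse classes afterwards.

Normalization here is a deliberately simple substitute for regularized-NB
variance stabilization: median-depth scaling + log1p with a mean-variance
trend standardization for HVG ranking.  All downstream stages consume this
normalization consistently.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .io import CountBundle


@dataclass(frozen=True)
class QCParams:
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 10000
    max_mito_fraction: float = 0.05
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not (0 < self.min_genes_per_cell < self.max_genes_per_cell):
            raise ValueError("need 0 < min_genes_per_cell < max_genes_per_cell")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must lie in [0, 1]")


class EmptyResultError(ValueError):
    """Raised when a filter removes every cell."""


def qc_filter(bundle: CountBundle, params: QCParams = QCParams()) -> CountBundle:
    """Retain cells with min <= detected genes <= max and mito fraction within
    bounds; genes and cell order are preserved. Idempotent."""
    counts = bundle.counts
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    total = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito_mask = (
        bundle.genes["symbol"].astype(str).str.startswith(params.mito_gene_prefix)
    ).to_numpy()
    mito = np.asarray(counts[mito_mask].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1.0), 0.0)
    keep = (
        (detected >= params.min_genes_per_cell)
        & (detected <= params.max_genes_per_cell)
        & (frac <= params.max_mito_fraction)
    )
    if not keep.any():
        raise EmptyResultError("QC filter removed every cell")
    return bundle.subset_cells(keep)


@dataclass
class NormalizedData:
    """Log-normalized expression with an HVG ranking.

    ``matrix`` is genes x cells over the full gene universe; ``hvg_indices``
    point into it (descending standardized variance).
    """

    matrix: sp.csr_matrix
    gene_ids: np.ndarray
    hvg_indices: np.ndarray

    @property
    def hvg_matrix(self) -> sp.csr_matrix:
        return self.matrix[self.hvg_indices]

    @property
    def hvg_gene_ids(self) -> np.ndarray:
        return self.gene_ids[self.hvg_indices]


def normalize_and_select_hvg(bundle: CountBundle, n_hvg: int = 3000) -> NormalizedData:
    """Median-depth log1p normalization plus trend-standardized HVG ranking.

    Per-gene variance of the normalized values is divided by a quadratic
    mean-variance trend fitted in log space; the ratio ranks genes.  Constant
    genes get standardized variance 0 and can never outrank a variable gene.
    """
    counts = sp.csr_matrix(bundle.counts, dtype=float)
    depth = np.asarray(counts.sum(axis=0)).ravel()
    if (depth <= 0).any():
        raise ValueError("cell with zero total count; run qc_filter first")
    target = float(np.median(depth))
    norm = counts.multiply(target / depth[None, :]).tocsr()
    norm.data = np.log1p(norm.data)

    n_cells = norm.shape[1]
    mean = np.asarray(norm.mean(axis=1)).ravel()
    sq = norm.multiply(norm).mean(axis=1)
    var = np.asarray(sq).ravel() - mean**2
    var = np.maximum(var, 0.0) * n_cells / max(n_cells - 1, 1)

    std_var = np.zeros_like(var)
    pos = (mean > 0) & (var > 0)
    if pos.sum() >= 3:
        lx, ly = np.log10(mean[pos]), np.log10(var[pos])
        coef = np.polyfit(lx, ly, deg=min(2, pos.sum() - 1))
        trend = 10 ** np.polyval(coef, np.log10(mean[pos]))
        std_var[pos] = var[pos] / np.maximum(trend, 1e-12)
    else:
        std_var[pos] = var[pos]

    # stable ranking: descending standardized variance, ties by gene order
    order = np.lexsort((np.arange(len(std_var)), -std_var))
    k = min(n_hvg, norm.shape[0])
    return NormalizedData(matrix=norm, gene_ids=bundle.gene_ids, hvg_indices=order[:k])


def select_pcs_elbow(
    normalized: sp.csr_matrix | np.ndarray,
    max_pcs: int = 17,
    drop_fraction: float = 0.001,
    n_pcs: int | None = None,
    random_state: int = 0,
) -> tuple[int, np.ndarray]:
    """PCA of the centered cells x genes matrix with an elbow rule.

    PCs are retained while each still explains at least ``drop_fraction`` of
    the total variance (default 0.1%); if the scree curve never falls below
    that floor — no elbow exists, as for isotropic data — the count falls back
    to the ``max_pcs`` cap.  ``n_pcs`` forces a fixed count (e.g. the 17-PC
    configuration used for cortical snRNA-seq cohorts).

    Returns ``(k, scores)`` with ``scores`` of shape cells x k.
    """
    X = normalized.toarray() if sp.issparse(normalized) else np.asarray(normalized)
    X = X.T  # cells x genes
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    n_comp = min(max_pcs + 1, X.shape[0] - 1, X.shape[1])
    if n_comp < 2:
        raise ValueError("matrix rank below 2")
    pca = PCA(n_components=n_comp, svd_solver="full" if min(X.shape) < 500 else "randomized",
              random_state=random_state)
    scores = pca.fit_transform(X)
    if np.sum(pca.explained_variance_) <= 0:
        raise ValueError("matrix rank below 2 (no variance)")
    evr = pca.explained_variance_ratio_
    if n_pcs is not None:
        k = min(n_pcs, scores.shape[1])
    else:
        k = min(max_pcs, len(evr))
        for i, r in enumerate(evr):
            if r < drop_fraction:
                k = min(i, max_pcs)
                break
        k = max(k, 1)
    return k, scores[:, :k]


@dataclass
class ClusterSolution:
    resolution: float
    labels: np.ndarray
    n_clusters: int
    mean_silhouette: float


def snn_graph(scores: np.ndarray, knn: int = 20, prune: float = 1.0 / 15.0) -> ig.Graph:
    """Shared-nearest-neighbor graph: k nearest neighbors (Euclidean, in PC
    space), edges weighted by the Jaccard overlap of neighbor sets, weights
    below ``prune`` dropped."""
    n = scores.shape[0]
    k = min(knn, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, idx = nn.kneighbors(scores)  # includes self in column 0
    neighbor_sets = [set(row) for row in idx]
    # candidate pairs: union of directed kNN relations, undirected
    pairs = {(min(i, int(j)), max(i, int(j))) for i in range(n) for j in idx[i]
             if int(j) != i}
    edges, weights = [], []
    for i, j in sorted(pairs):
        inter = len(neighbor_sets[i] & neighbor_sets[j])
        union = len(neighbor_sets[i] | neighbor_sets[j])
        w = inter / union if union else 0.0
        if w >= prune:
            edges.append((i, j))
            weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


_SINGLETON_SILHOUETTE = -1.0  # sentinel when silhouette is undefined


def _mean_silhouette(
    scores: np.ndarray,
    labels: np.ndarray,
    subsample: int = 10000,
    seed: int = 0,
) -> float:
    n_labels = len(np.unique(labels))
    if n_labels < 2 or n_labels >= len(labels):  # silhouette undefined
        return _SINGLETON_SILHOUETTE
    n = scores.shape[0]
    if n > 2 * subsample:
        rng = np.random.default_rng(seed)
        pick = rng.choice(n, size=subsample, replace=False)
        sub_labels = labels[pick]
        if len(np.unique(sub_labels)) < 2:
            return _SINGLETON_SILHOUETTE
        return float(silhouette_score(scores[pick], sub_labels, metric="euclidean"))
    return float(silhouette_score(scores, labels, metric="euclidean"))


def cluster_with_silhouette(
    scores: np.ndarray,
    resolution_grid: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6),
    knn: int = 20,
    prune: float = 1.0 / 15.0,
    silhouette_subsample: int = 10000,
    seed: int = 0,
) -> tuple[ClusterSolution, list[ClusterSolution]]:
    """Louvain on the SNN graph at each resolution; the solution with the
    highest mean silhouette width (PC space, Euclidean) wins, ties going to the
    lower resolution.  Single-cluster solutions get the -1 sentinel and are
    only selected if every solution is single-cluster."""
    if scores.shape[0] < knn + 1:
        raise ValueError(f"need at least knn+1={knn + 1} cells")
    if np.all(scores == scores[0]):
        # all cells coincide: every partition is arbitrary, report one cluster
        solutions = [
            ClusterSolution(
                resolution=float(res),
                labels=np.zeros(scores.shape[0], dtype=int),
                n_clusters=1,
                mean_silhouette=_SINGLETON_SILHOUETTE,
            )
            for res in sorted(resolution_grid)
        ]
        return solutions[0], solutions
    g = snn_graph(scores, knn=knn, prune=prune)
    # igraph's Louvain draws from a global RNG; pin it for reproducibility
    ig.set_random_number_generator(random.Random(seed))
    solutions: list[ClusterSolution] = []
    for res in sorted(resolution_grid):
        part = g.community_multilevel(weights="weight" if g.ecount() else None,
                                      resolution=float(res))
        labels = np.asarray(part.membership)
        sil = _mean_silhouette(scores, labels, subsample=silhouette_subsample, seed=seed)
        solutions.append(
            ClusterSolution(
                resolution=float(res),
                labels=labels,
                n_clusters=int(len(np.unique(labels))),
                mean_silhouette=sil,
            )
        )
    best = max(solutions, key=lambda s: (s.mean_silhouette, -s.resolution))
    return best, solutions


@dataclass
class AnnotatedClusters:
    """Per-cluster cell-type assignment with its marker score."""

    assignments: pd.DataFrame  # cluster, cell_type, score, confident
    cell_labels: np.ndarray  # per-cell assigned type name

    def relabel_cells(self, labels: np.ndarray) -> np.ndarray:
        lut = dict(zip(self.assignments["cluster"], self.assignments["cell_type"]))
        return np.array([lut[c] for c in labels])


def annotate_clusters(
    normalized: sp.csr_matrix | np.ndarray,
    gene_ids: np.ndarray,
    cluster_labels: np.ndarray,
    marker_table: pd.DataFrame,
    confidence_factor: float = 0.25,
) -> AnnotatedClusters:
    """Specificity-weighted marker z-score annotation.

    For each gene, cluster-mean expression is z-scored *across clusters*; each
    marker contributes ``weight * z`` to its cell type's cluster score, with
    ``weight = 1 / (number of cell types listing the marker)``.  A cluster is
    assigned the argmax type, or "unknown" when the top score falls below
    ``confidence_factor * sqrt(cluster size)``.
    """
    if marker_table is None or len(marker_table) == 0:
        raise ValueError("marker table is empty")
    X = sp.csr_matrix(normalized)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    present = marker_table[marker_table["gene"].isin(gene_pos)]
    absent = sorted(set(marker_table["gene"]) - set(present["gene"]))
    if absent:
        warnings.warn(f"{len(absent)} markers absent from gene universe; ignored")
    if len(present) == 0:
        raise ValueError("no marker genes present in the gene universe")

    clusters = np.unique(cluster_labels)
    cl_means = np.column_stack(
        [
            np.asarray(X[:, cluster_labels == c].mean(axis=1)).ravel()
            for c in clusters
        ]
    )  # genes x clusters
    mu = cl_means.mean(axis=1, keepdims=True)
    sd = cl_means.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (cl_means - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    listing_counts = present.groupby("gene")["cell_type"].nunique()
    types = sorted(present["cell_type"].unique())
    scores = np.zeros((len(types), len(clusters)))
    for ti, t in enumerate(types):
        for g in present.loc[present["cell_type"] == t, "gene"]:
            w = 1.0 / listing_counts[g]
            scores[ti] += w * z[gene_pos[g]]

    sizes = np.array([(cluster_labels == c).sum() for c in clusters])
    rows = []
    for ci, c in enumerate(clusters):
        best_ti = int(np.argmax(scores[:, ci]))
        top = float(scores[best_ti, ci])
        confident = top >= confidence_factor * np.sqrt(sizes[ci])
        rows.append(
            {
                "cluster": c,
                "cell_type": types[best_ti] if confident else "unknown",
                "score": top,
                "confident": bool(confident),
            }
        )
    assignments = pd.DataFrame(rows)
    ann = AnnotatedClusters(assignments=assignments, cell_labels=np.empty(0, dtype=object))
    ann.cell_labels = ann.relabel_cells(cluster_labels)
    return ann


def merge_labels(annotated: AnnotatedClusters, merge_map: dict[str, str]) -> AnnotatedClusters:
    """Replace fine labels by coarse ones (e.g. layer-resolved excitatory
    neuron subclusters -> "Excitatory neuron"); cluster ids are preserved and
    unmapped labels pass through."""
    assignments = annotated.assignments.copy()
    assignments["cell_type"] = assignments["cell_type"].map(
        lambda x: merge_map.get(x, x)
    )
    labels = np.array([merge_map.get(x, x) for x in annotated.cell_labels])
    return AnnotatedClusters(assignments=assignments, cell_labels=labels)
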