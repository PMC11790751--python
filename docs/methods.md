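# Methods

This note records the models, parameter choices and numerical conventions
behind `sccompare`, and what the synthetic validation does and does not show.

## Synthetic paired cohorts

Counts are negative binomial via a gamma–Poisson mixture: for gene g and cell
c with mean μ_gc and shared dispersion θ (gamma shape; default 2.0), the
count is Poisson(Gamma(θ, μ_gc/θ)), giving Var = μ + μ²/θ. Background genes
sit at `baseline_mean` (default 2.0 counts, a typical droplet-depth scale for
a 2000-gene universe). Cell identity is purely compositional: each of
`n_cell_types` types owns a disjoint block of `n_markers_per_type` marker
genes whose mean is multiplied by `marker_fold` (default 8) in that type.

Planted differential expression acts multiplicatively on the mean: a gene
planted with log2 effect e has its mean multiplied by 2^e in *disease* cells
of the stated cell type. Category semantics fix the per-cohort effects:
shared_up (+|e|, +|e|), shared_down (−|e|, −|e|), specific_A (e, 0),
specific_B (0, e), contrasting (e, −e). The default study configuration
plants 10 genes per category at |e| = 1.5 in one cell type, with 200 cells
per condition per type (2 donors × 200 cells per condition, two cell types)
— sizes at which the rank-sum test has essentially full power at this effect
size, so recovery failures isolate classification logic rather than power.

Ligand-receptor channels are wired as (ligand in sender type) → (receptor,
TF, five regulon targets in receiver type); in cohorts where a channel is
active all six genes have their means multiplied by `lr_fold` (default 20,
enough to place them at the top of the cluster's expression percentile).
Priors generated alongside: one gene set per planted category (planted genes
padded to `set_size` with background genes), one set per channel (its regulon
targets), uniform random decoy sets; a master regulator with sign-consistent
edges to every shared planted gene plus random activating/inhibiting decoy
edges; and the LR/receptor-TF/regulon/marker tables matching the wiring.

Reproducibility: one master seed; cohorts A and B, and the prior generator,
draw from fixed-offset child streams (`default_rng([seed, k])`), so cohorts
are mutually independent but byte-reproducible. Donor effects (lognormal
multiplicative factor per donor) exist but default off, matching an analysis
that pools cells across donors.

What the generator does **not** emulate: ambient RNA, doublets, batch
structure beyond donor factors, gene-gene correlation, mean-dependent
dispersion, or realistic effect-size distributions (the planted |e| = 1.5 is
chosen for testability). Passing recovery tests therefore demonstrates the
correctness of the statistical machinery under its own assumptions, not
performance on real tissue.

## Preprocessing

QC retains cells with 200 ≤ detected genes ≤ 10000 and mitochondrial count
fraction ≤ 5% (gene-symbol prefix `MT-`, computed on raw counts; both
boundaries inclusive on the retained side). The `max_genes` cap doubles as
the doublet proxy; no simulation-based doublet detection is performed.

Normalization is median-depth scaling plus log1p. This is a deliberately
simple substitute for regularized negative-binomial variance stabilization;
all downstream stages consume it consistently. HVG ranking divides each
gene's variance of normalized values by a quadratic mean-variance trend
fitted in log10 space, keeping the top `n_hvg` (default 3000).

A known property worth naming: depth normalization redistributes any net
imbalance of the planted (or real) perturbation onto all other genes. In the
default study, cohort A's planted effects are net-upward, so background
genes in A acquire a small opposite shift and their null p-values are
slightly anti-conservative; cohort B's effects happen to balance. The
consequence is visible in the worked example (extra `specific_A` calls) and
in the acceptance numbers; it is a faithful rendition of what this
normalization does to real asymmetric perturbations.

PCA runs on the centered cells × HVG matrix. The elbow keeps PCs while each
still explains ≥ 0.1% of total variance and otherwise falls back to the
`max_pcs` cap (default 17, the configuration used for cortical snRNA-seq);
a fixed `n_pcs` override is available. The stated drop-based rule is
equivalent in the cases that matter here and ill-posed for flat scree
curves, hence this formulation.

Clustering builds a shared-nearest-neighbor graph (k = 20 Euclidean
neighbors in PC space, Jaccard edge weights, pruning below 1/15 — common
practice, config-exposed), runs Louvain at each resolution in
{0.2, …, 1.6}, and selects the solution maximizing mean silhouette width in
PC space (ties → lower resolution). Single-cluster solutions get a −1
sentinel and are never selected unless every solution is single-cluster; on
> 20k cells the silhouette uses a seeded 10k subsample. igraph's Louvain
draws from a global RNG, which is pinned per call for determinism.

Annotation is a specificity-weighted marker z-score: per gene, cluster-mean
expression is z-scored across clusters; each marker contributes
z / (number of cell types listing it) to its type's cluster score; the
argmax type wins unless the top score falls below 0.25 × √(cluster size), in
which case the cluster is labeled `unknown`. This is a simplified
reinterpretation of marker-database annotation scores, not a reimplementation
of any published tool. Fine labels (e.g. layer-resolved neuron subclusters)
can be merged into coarse classes by an explicit map.

## Differential expression

Cells are the replication unit (mirroring standard per-cell-type marker
tests); donor-level pseudobulk is intentionally out of the default path.
Genes detected in ≥ `min_pct` (default 0.10) of either group are tested.
The rank-sum p-value is exact — a subset-sum dynamic program over doubled
midranks, so ties remain exact — when min(n₁, n₂) < 10, and a tie-corrected
normal approximation with 0.5 continuity correction otherwise; two-sided
p = P(|W − E[W]| ≥ |w − E[W]|), the symmetric-deviation convention that
remains well-defined under tie-induced asymmetry. Zero p-values are floored
to the smallest positive double before BH. BH is applied within each cell
type over its tested genes. The fold-change base is log2 with the
mean(expm1)+1 convention; thresholds elsewhere are on this scale.

## Cross-disease classification

Significance in a cohort means FDR < `fdr_max` (0.05) and |log2FC| >
`lfc_min` (0.10). Both significant and same sign → shared_up/shared_down;
both significant and opposite signs → contrasting; significant in exactly
one cohort *and* nominal p > `nonsig_p_min` (0.5) in the other →
specific; everything else, including genes tested in only one cohort, is
explicitly `unclassified`, making the partition total. The specific rule
uses only the nominal p in the other cohort, as the rule is stated — no
fold-change condition on that leg.

Structural ceiling: a gene with *exactly* zero effect in the other cohort
has a uniform nominal p there, so the clearly-null condition admits it with
probability ≈ 1/2. Recall for genuinely specific genes is therefore capped
near 0.5 regardless of effect size or cell number; this is a property of
the rule, not of the implementation, and the acceptance suite reports it
honestly (the specific-category sensitivity check fails by design of the
rule). The Fisher overlap test uses the genes tested in both cohorts as its
universe and the same significance rule as classification.

## Enrichment

One-sided hypergeometric upper tail, universe = genes tested for DE in that
cell type (avoiding detection-bias inflation), BH within each
(cell type × category × collection) stratum. "More than five hits" is
interpreted strictly as k ≥ 6. Direction labels: majority sign of the hit
genes (Equal on ties) in shared mode; in contrasting mode every hit must
carry opposite per-cohort signs and the label is the per-cohort arrow pair.

## Signed networks and perturbagens

The subnetwork for a category is induced on its genes plus any prior
regulator with ≥ 1 target in the category; self-loops are dropped, duplicate
edges collapse to their common sign, and sign-conflicting duplicates are
dropped with a warning (conservative). Influence propagates along shortest
directed paths within `max_depth` (default 5) as the product of edge signs;
targets whose equal-length shortest paths disagree are excluded rather than
majority-voted. The perturbagen score of a candidate is the larger count,
over modulation directions d ∈ {+1, −1}, of DEG-signed reachable nodes with
d × influence = −(observed sign); ties resolve to inhibition (−1), the
pharmacologically common mode. This shortest-path reversal count is this
package's own operationalization of "downstream targets whose expression the
perturbagen can reverse"; it makes no claim of numerical equivalence with
steady-state network-perturbation methods. Degree ranking counts total
(in + out) connections.

## Cell-cell communication

Evidence(gene, cluster) = √(detection fraction × percentile of cluster-mean
among all genes), in [0, 1]; cluster means are rounded to 10 decimals before
ranking so cell order cannot break ties. S_inter is the min of ligand
evidence in the sender and receptor evidence in the receiver; S_intra is the
best, over TFs linked to the receptor, of √(TF evidence × mean target
evidence), zero when no receptor→TF link exists. The joint threshold 0.8 is
inclusive. Shared processes across cohorts use nominal p < 0.05 (an adjusted
mode is available) over the regulon-target universe restricted to the
expression universe. These score formulas are a simplified reinterpretation
of intra/intercellular communication evidence scoring that preserves the
published contract (range [0, 1], higher = stronger, joint thresholding at
0.8), without claiming numerical equivalence to any specific tool.

## Pipeline

`run_all` executes the stages in order, writing TSV outputs and a manifest
(seed, SHA-256 input digests, per-stage row counts); any stage failure is
recorded and downstream stages are skipped. Per-cell-type DE runs only for
types with ≥ 50 cells (configurable) in both conditions of both cohorts.
Stage subcommands re-derive the normalized matrix deterministically from the
bundle plus the annotation TSV, so intermediates stay small and plain-text.
All paper-derived defaults (200/10000 genes, 5% mito, 3000 HVGs, 17 max PCs,
FDR 0.05, logFC 0.10, nonsignificance p 0.5, ≥ 6 ORA hits, 0.8 communication
threshold) are named config fields.

## Problem sizes used in validation

The acceptance computations use: null calibration at 2000 genes, 50 vs 50
cells; BH FDR on 20 mixtures of m = 2000 with π₀ = 0.9; category recovery
over repeated paired studies at the default configuration (10 genes per
category, |e| = 1.5, 200 cells per group); enrichment/network/communication
recovery over repeated replicates of the same configuration; clustering
recovery at 3 types × 200 cells with marker fold 8. Oracle-equivalence
checks run the exact Wilcoxon against full permutation enumeration
(n₁ + n₂ ≤ 10), Fisher against full-table enumeration (totals ≤ 60),
hypergeometric p against direct tail summation (N ≤ 200), and perturbagen
scores against exhaustive simple-path enumeration (≤ 12 nodes).

## Known limitations

- The normalization substitute ignores mean-variance regularization; with
  strongly asymmetric perturbations it transfers composition bias to null
  genes (see above).
- Specific-category recall is capped near 0.5 by the clearly-null rule.
- The perturbagen and communication scores are reinterpretations; rankings,
  not absolute values, are the meaningful output.
- Marker annotation assumes marker sets that are at least partially disjoint;
  fully overlapping marker tables drive scores toward the `unknown` floor.
- The SNN/Louvain stack targets up to a few tens of thousands of cells;
  silhouette subsampling is the only large-n concession implemented.
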