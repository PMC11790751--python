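"""Per-cell-type differential expression: Wilcoxon rank-sum, BH, fold changes.

The test is the two-sample Wilcoxon rank-sum (Mann-Whitney) on normalized
expression, with midranks for ties.  When both groups have at least 10
observations a normal approximation with tie-corrected variance and a 0.5
continuity correction is used; below that the exact permutation distribution
of the rank sum is computed (a subset-sum dynamic program over doubled
midranks, so tied data stay exact).  Two-sided p-values are
``P(|W - E[W]| >= |w_obs - E[W]|)`` under random assignment, which reduces to
the usual two-tailed sum and handles tie-induced asymmetry correctly.

Fold changes follow the single-cell convention
``log2((mean(expm1(x_disease)) + 1) / (mean(expm1(x_control)) + 1))`` on
log1p-normalized values; the +1 pseudocount keeps the ratio finite for
all-zero groups.  Benjamini-Hochberg adjustment is applied within each cell
type across the tested genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata

_EXACT_MAX_MIN_N = 10  # exact path when min(n1, n2) < this
_TINY_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class DEGRecord:
    gene: str
    cell_type: str
    log2fc: float
    p_nominal: float
    fdr: float
    pct_disease: float
    pct_control: float


def _rank_sum_exact_p(pooled: np.ndarray, n1: int) -> float:
    """Exact two-sided permutation p for the rank sum of the first group.

    Works on doubled midranks (integers even under ties) via a count DP over
    all C(N, n1) assignments.
    """
    N = len(pooled)
    ranks2 = np.round(2.0 * rankdata(pooled)).astype(np.int64)
    w_obs = int(ranks2[:n1].sum())
    dev = abs(w_obs - n1 * (N + 1))  # |W - E[W]|, doubled scale

    # W_group1 - E1 = -(W_group2 - E2), so the DP can always run over the
    # smaller group without changing the deviation being tail-summed.
    k = min(n1, N - n1)
    mean2 = k * (N + 1)
    max_sum = int(np.sort(ranks2)[-k:].sum())
    # dp[j, s] = number of j-subsets with doubled-rank sum s
    dp = np.zeros((k + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for j in range(k, 0, -1):
            dp[j, r:] += dp[j - 1, : max_sum + 1 - r]
    counts = dp[k]
    total = counts.sum()
    sums = np.arange(max_sum + 1)
    extreme = np.abs(sums - mean2) >= dev - 1e-9
    return float(min(1.0, counts[extreme].sum() / total))


def _normal_approx_p(pooled: np.ndarray, n1: int) -> float:
    N = len(pooled)
    n2 = N - n1
    ranks = rankdata(pooled)
    w = ranks[:n1].sum()
    mean = n1 * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0
    dev = abs(w - mean)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(z)))


def wilcoxon_test(
    values_disease: np.ndarray, values_control: np.ndarray
) -> tuple[float, float]:
    """Two-sample rank-sum test; returns (rank-sum statistic of the disease
    group, two-sided p)."""
    x = np.asarray(values_disease, dtype=float).ravel()
    y = np.asarray(values_control, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    w = float(rankdata(pooled)[: len(x)].sum())
    if min(len(x), len(y)) >= _EXACT_MAX_MIN_N:
        p = _normal_approx_p(pooled, len(x))
    else:
        p = _rank_sum_exact_p(pooled, len(x))
    return w, max(p, _TINY_P)


def log2_fold_change(values_disease: np.ndarray, values_control: np.ndarray) -> float:
    """Seurat-style log2 fold change of de-logged group means (+1 pseudocount)."""
    md = float(np.mean(np.expm1(np.asarray(values_disease, dtype=float))))
    mc = float(np.mean(np.expm1(np.asarray(values_control, dtype=float))))
    return float(np.log2((md + 1.0) / (mc + 1.0)))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _wilcoxon_normal_many(Xd: np.ndarray, Xc: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected normal-approximation p over genes (rows)."""
    n1, n2 = Xd.shape[1], Xc.shape[1]
    N = n1 + n2
    pooled = np.hstack([Xd, Xc])
    ranks = rankdata(pooled, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    mean = n1 * (N + 1) / 2.0
    # per-row tie term via sorted run lengths
    srt = np.sort(pooled, axis=1)
    tie_terms = np.empty(pooled.shape[0])
    for i in range(pooled.shape[0]):
        _, cnt = np.unique(srt[i], return_counts=True)
        tie_terms[i] = float((cnt**3 - cnt).sum())
    var = n1 * n2 / 12.0 * ((N + 1) - tie_terms / (N * (N - 1)))
    dev = np.abs(w - mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, np.maximum(dev - 0.5, 0.0) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    p = np.where(var > 0, 2.0 * norm.sf(z), 1.0)
    return np.clip(p, _TINY_P, 1.0)


def run_de(
    normalized: sp.csr_matrix | np.ndarray,
    gene_ids: np.ndarray,
    conditions: np.ndarray,
    cell_type_labels: np.ndarray,
    cell_type: str,
    min_pct: float = 0.1,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Disease-vs-control DE within one cell type.

    Genes detected in at least ``min_pct`` of either group are tested; BH is
    applied within the cell type over the tested genes.  Returns a DataFrame
    sorted by nominal p with the :class:`DEGRecord` columns; an empty frame
    (with a warning) when the cell type lacks ``min_cells`` cells in either
    condition.
    """
    conditions = np.asarray(conditions)
    cell_type_labels = np.asarray(cell_type_labels)
    in_type = cell_type_labels == cell_type
    d_mask = in_type & (conditions == "disease")
    c_mask = in_type & (conditions == "control")
    cols = ["gene", "cell_type", "log2fc", "p_nominal", "fdr", "pct_disease", "pct_control"]
    if d_mask.sum() < min_cells or c_mask.sum() < min_cells:
        warnings.warn(
            f"cell type {cell_type!r}: fewer than {min_cells} cells in one "
            "condition; skipping DE"
        )
        return pd.DataFrame(columns=cols)

    X = sp.csr_matrix(normalized)
    Xd = X[:, np.flatnonzero(d_mask)]
    Xc = X[:, np.flatnonzero(c_mask)]
    n1, n2 = Xd.shape[1], Xc.shape[1]
    pct_d = np.asarray((Xd > 0).sum(axis=1)).ravel() / n1
    pct_c = np.asarray((Xc > 0).sum(axis=1)).ravel() / n2
    tested = np.flatnonzero((pct_d >= min_pct) | (pct_c >= min_pct))
    if tested.size == 0:
        return pd.DataFrame(columns=cols)

    Dd = Xd[tested].toarray()
    Dc = Xc[tested].toarray()
    if min(n1, n2) >= _EXACT_MAX_MIN_N:
        p = _wilcoxon_normal_many(Dd, Dc)
    else:
        p = np.array(
            [wilcoxon_test(Dd[i], Dc[i])[1] for i in range(len(tested))]
        )
    p = np.maximum(p, _TINY_P)
    lfc = np.log2((np.expm1(Dd).mean(axis=1) + 1.0) / (np.expm1(Dc).mean(axis=1) + 1.0))
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "gene": np.asarray(gene_ids)[tested],
            "cell_type": cell_type,
            "log2fc": lfc,
            "p_nominal": p,
            "fdr": fdr,
            "pct_disease": pct_d[tested],
            "pct_control": pct_c[tested],
        }
    )
    return out.sort_values("p_nominal", kind="mergesort").reset_index(drop=True)
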