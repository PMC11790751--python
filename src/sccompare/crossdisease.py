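"""Cross-cohort DEG classification: shared, disease-specific, contrasting.

A gene is *significant* in a cohort when its FDR is below ``fdr_max`` and its
absolute log2 fold change exceeds ``lfc_min``.  Genes significant in both
cohorts are ``shared_up`` / ``shared_down`` when the fold changes agree in
sign and ``contrasting`` when they disagree; a gene significant in exactly one
cohort is disease-specific only when it is *clearly* null in the other
(nominal p above ``nonsig_p_min``, a deliberately conservative gap that keeps
borderline genes out of the specific buckets).  Everything else — including
genes tested in only one cohort — is ``unclassified``, making the partition
total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

CATEGORIES = (
    "shared_up",
    "shared_down",
    "specific_A",
    "specific_B",
    "contrasting",
    "unclassified",
)


@dataclass(frozen=True)
class GeneStats:
    """One cohort's DE evidence for a gene."""

    log2fc: float
    p: float
    fdr: float


@dataclass(frozen=True)
class Thresholds:
    fdr_max: float = 0.05
    lfc_min: float = 0.10
    nonsig_p_min: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_max < self.nonsig_p_min <= 1.0):
            raise ValueError("need 0 < fdr_max < nonsig_p_min <= 1")
        if self.lfc_min <= 0:
            raise ValueError("lfc_min must be positive")


def _significant(s: GeneStats, thr: Thresholds) -> bool:
    return s.fdr < thr.fdr_max and abs(s.log2fc) > thr.lfc_min


def classify_gene(
    stats_a: GeneStats | None,
    stats_b: GeneStats | None,
    thresholds: Thresholds = Thresholds(),
) -> str:
    """Assign exactly one cross-disease category to a gene."""
    if stats_a is None or stats_b is None:
        return "unclassified"
    sig_a = _significant(stats_a, thresholds)
    sig_b = _significant(stats_b, thresholds)
    if sig_a and sig_b:
        sa, sb = np.sign(stats_a.log2fc), np.sign(stats_b.log2fc)
        if sa == 0 or sb == 0:  # sign undefined (cannot occur when lfc_min > 0)
            return "unclassified"
        if sa == sb:
            return "shared_up" if sa > 0 else "shared_down"
        return "contrasting"
    if sig_a and stats_b.p > thresholds.nonsig_p_min:
        return "specific_A"
    if sig_b and stats_a.p > thresholds.nonsig_p_min:
        return "specific_B"
    return "unclassified"


def classify_table(
    degs_a: pd.DataFrame,
    degs_b: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Classify every (gene, cell_type) tested in either cohort.

    Inputs are ``run_de`` tables (possibly concatenated over cell types).
    Genes tested in only one cohort come back ``unclassified`` with a reason
    flag.
    """
    key = ["gene", "cell_type"]
    cols = ["log2fc", "p_nominal", "fdr"]
    merged = degs_a[key + cols].merge(
        degs_b[key + cols], on=key, how="outer", suffixes=("_A", "_B")
    )
    categories, reasons = [], []
    for row in merged.itertuples(index=False):
        if np.isnan(row.p_nominal_A) or np.isnan(row.p_nominal_B):
            categories.append("unclassified")
            reasons.append("untested_in_one_cohort")
            continue
        sa = GeneStats(row.log2fc_A, row.p_nominal_A, row.fdr_A)
        sb = GeneStats(row.log2fc_B, row.p_nominal_B, row.fdr_B)
        categories.append(classify_gene(sa, sb, thresholds))
        reasons.append("")
    out = merged.rename(
        columns={"p_nominal_A": "p_A", "p_nominal_B": "p_B"}
    )
    out["category"] = categories
    out["reason"] = reasons
    return out


def overlap_fisher(
    n_sig_a_only: int, n_sig_b_only: int, n_sig_both: int, n_neither: int
) -> float:
    """Two-sided Fisher exact p for the 2x2 significance-overlap table over
    the genes tested in both cohorts."""
    counts = (n_sig_a_only, n_sig_b_only, n_sig_both, n_neither)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    table = np.array([[n_sig_both, n_sig_a_only], [n_sig_b_only, n_neither]])
    return float(fisher_exact(table, alternative="two-sided")[1])


def overlap_test(calls: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> float:
    """Fisher overlap p computed from a ``classify_table`` output (one cell
    type), using the same significance rule as classification."""

    def sig(prefix: str) -> pd.Series:
        return (calls[f"fdr_{prefix}"] < thresholds.fdr_max) & (
            calls[f"log2fc_{prefix}"].abs() > thresholds.lfc_min
        )

    tested = calls["reason"] != "untested_in_one_cohort"
    a, b = sig("A") & tested, sig("B") & tested
    return overlap_fisher(
        int((a & ~b).sum()), int((~a & b).sum()), int((a & b).sum()),
        int((tested & ~a & ~b).sum()),
    )


def venn_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Category counts per cell type (the numbers behind a Venn diagram)."""
    if len(calls) == 0:
        return pd.DataFrame(columns=["cell_type", *CATEGORIES])
    rows = []
    for ct, sub in calls.groupby("cell_type"):
        counts = sub["category"].value_counts()
        rows.append(
            {"cell_type": ct, **{c: int(counts.get(c, 0)) for c in CATEGORIES}}
        )
    return pd.DataFrame(rows)
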