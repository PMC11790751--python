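"""Hypergeometric overrepresentation analysis with directionality labels.

For a DEG list of size ``n`` drawn from a universe of ``N`` tested genes, a
gene set with ``K`` members in the universe and ``k`` DEG hits is scored by
the upper-tail hypergeometric probability ``P(X >= k)``.  P-values are BH
adjusted across the tested sets, and a set is flagged significant when the
adjusted p is below 0.05 *and* it has more than five DEG hits (``k >= 6``),
the minimum-hit rule used for pathway reporting.

Direction labels summarize where the hit genes moved: in shared mode a set is
"Up"/"Down" by majority sign ("Equal" on ties); in contrasting mode the label
is the pair of opposite per-cohort arrows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .degtest import bh_adjust


def ora(
    deg_genes: set[str] | list[str],
    universe: set[str] | list[str],
    gene_sets: dict[str, tuple[str, list[str]]],
    min_hits: int = 6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric ORA of ``deg_genes`` against ``gene_sets``.

    Sets are intersected with the universe first; empty intersections are
    skipped.  Returns a DataFrame sorted by p with columns
    ``set_id, set_name, k, K, n, N, p, p_adj, significant``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    deg = set(deg_genes)
    stray = deg - universe
    if stray:
        raise ValueError(
            f"{len(stray)} DEG genes are outside the universe (e.g. "
            f"{sorted(stray)[:3]})"
        )
    N, n = len(universe), len(deg)
    rows = []
    for set_id, (name, members) in gene_sets.items():
        in_univ = set(members) & universe
        K = len(in_univ)
        if K == 0:
            continue
        k = len(in_univ & deg)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"set_id": set_id, "set_name": name, "k": k, "K": K, "n": n, "N": N,
             "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["set_id", "set_name", "k", "K", "n", "N", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = (out["p_adj"] < alpha) & (out["k"] >= min_hits)
        out = out.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def direction_label(hit_signs, mode: str = "shared") -> str | tuple[str, str]:
    """Summarize the direction of change among a set's hit genes.

    ``shared`` mode takes one sign per gene (+1/-1) and returns "Up", "Down"
    or "Equal" by majority.  ``contrasting`` mode takes (sign_A, sign_B) pairs
    that must be opposite for every gene, and returns the per-cohort arrow
    pair, e.g. ``("up", "down")`` when cohort A's majority rises.
    """
    hit_signs = list(hit_signs)
    if not hit_signs:
        raise ValueError("empty hit list")
    if mode == "shared":
        up = sum(1 for s in hit_signs if s > 0)
        down = sum(1 for s in hit_signs if s < 0)
        if up > down:
            return "Up"
        if down > up:
            return "Down"
        return "Equal"
    if mode == "contrasting":
        for sa, sb in hit_signs:
            if sa == 0 or sb == 0 or np.sign(sa) == np.sign(sb):
                raise ValueError("contrasting mode requires opposite nonzero signs")
        up_a = sum(1 for sa, _ in hit_signs if sa > 0)
        down_a = len(hit_signs) - up_a
        if up_a >= down_a:
            return ("up", "down")
        return ("down", "up")
    raise ValueError(f"unknown mode {mode!r}")


def enrich_category(
    calls: pd.DataFrame,
    category: str,
    universe: set[str],
    gene_sets: dict[str, tuple[str, list[str]]],
    min_hits: int = 6,
) -> pd.DataFrame:
    """ORA of one cross-disease category's genes with direction labels.

    ``calls`` is a ``classify_table`` output restricted to one cell type; the
    universe is the set of genes tested in both cohorts for that cell type.
    """
    sub = calls[calls["category"] == category]
    deg = set(sub["gene"]) & universe
    res = ora(deg, universe, gene_sets, min_hits=min_hits)
    sign_a = dict(zip(sub["gene"], np.sign(sub["log2fc_A"])))
    sign_b = dict(zip(sub["gene"], np.sign(sub["log2fc_B"])))
    labels = []
    for _, row in res.iterrows():
        hits = set(gene_sets[row["set_id"]][1]) & deg
        if not hits:
            labels.append("")
            continue
        if category == "contrasting":
            pair = direction_label(
                [(sign_a[g], sign_b[g]) for g in hits], mode="contrasting"
            )
            labels.append(f"A_{pair[0]}|B_{pair[1]}")
        else:
            labels.append(direction_label([sign_a[g] for g in hits], mode="shared"))
    res["direction"] = labels
    return res
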