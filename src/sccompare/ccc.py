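"""Ligand-receptor communication scoring between annotated cell types.

Evidence that a gene is actively expressed in a cluster is the geometric mean
of (i) the fraction of the cluster's cells detecting it and (ii) the
percentile of its cluster-mean expression among all genes' cluster means, so
it lives in [0, 1] with 1 for a universally detected, top-expressed gene.

For a ligand-receptor pair between a sender and a receiver cluster:

* ``S_inter = min(evidence(ligand, sender), evidence(receptor, receiver))`` —
  intercellular evidence, limited by the weaker partner;
* ``S_intra`` — intracellular response evidence in the receiver: over the
  transcription factors linked to the receptor, the best geometric mean of
  the TF's own evidence and the mean evidence of its regulon targets (0 when
  no receptor->TF link exists).

Pairs clearing a joint threshold (default 0.8 on both scores) are retained;
cross-cohort comparison then asks which processes enriched in the retained
pairs' target genes are shared by both cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .enrich import ora


@dataclass
class CommScorePair:
    sender: str
    receiver: str
    ligand: str
    receptor: str
    s_inter: float
    s_intra: float
    best_tf: str | None = None
    target_genes: list[str] = field(default_factory=list)


class ClusterEvidence:
    """Per-cluster expression evidence, cached over genes.

    ``matrix`` is normalized genes x cells; ``labels`` assigns each cell to a
    cluster (annotated cell-type names).
    """

    def __init__(
        self,
        matrix: sp.csr_matrix | np.ndarray,
        gene_ids: np.ndarray,
        labels: np.ndarray,
    ) -> None:
        self.matrix = sp.csr_matrix(matrix)
        self.gene_ids = np.asarray(gene_ids)
        self.gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
        self.labels = np.asarray(labels)
        self._cache: dict[str, np.ndarray] = {}

    def _cluster_evidence(self, cluster: str) -> np.ndarray:
        if cluster in self._cache:
            return self._cache[cluster]
        cols = np.flatnonzero(self.labels == cluster)
        if cols.size == 0:
            raise ValueError(f"cluster {cluster!r} is empty")
        sub = self.matrix[:, cols]
        frac = np.asarray((sub > 0).sum(axis=1)).ravel() / cols.size
        means = np.asarray(sub.mean(axis=1)).ravel()
        # round before ranking so summation order cannot break exact ties
        pct = rankdata(np.round(means, 10)) / len(means)  # top gene -> 1
        ev = np.sqrt(frac * pct)
        self._cache[cluster] = ev
        return ev

    def evidence(self, gene: str, cluster: str) -> float:
        """Expression evidence of one gene in one cluster, in [0, 1]."""
        if gene not in self.gene_pos:
            raise KeyError(f"gene {gene!r} absent from the universe")
        return float(self._cluster_evidence(cluster)[self.gene_pos[gene]])


def score_pair(
    ev: ClusterEvidence,
    ligand: str,
    receptor: str,
    sender: str,
    receiver: str,
    receptor_tf: pd.DataFrame,
    regulons: pd.DataFrame,
) -> CommScorePair:
    """Score one ligand-receptor pair for one sender->receiver cluster pair."""
    s_inter = min(ev.evidence(ligand, sender), ev.evidence(receptor, receiver))
    tfs = receptor_tf.loc[receptor_tf["receptor"] == receptor, "tf"].unique()
    best_tf, best_intra, best_targets = None, 0.0, []
    for tf in tfs:
        if tf not in ev.gene_pos:
            continue
        targets = [
            t
            for t in regulons.loc[regulons["tf"] == tf, "target"].unique()
            if t in ev.gene_pos
        ]
        target_ev = (
            float(np.mean([ev.evidence(t, receiver) for t in targets]))
            if targets
            else 0.0
        )
        s = float(np.sqrt(ev.evidence(tf, receiver) * target_ev))
        if s > best_intra:
            best_tf, best_intra, best_targets = tf, s, targets
    return CommScorePair(
        sender=sender,
        receiver=receiver,
        ligand=ligand,
        receptor=receptor,
        s_inter=float(s_inter),
        s_intra=best_intra,
        best_tf=best_tf,
        target_genes=best_targets,
    )


def score_all_pairs(
    ev: ClusterEvidence,
    lr_pairs: pd.DataFrame,
    receptor_tf: pd.DataFrame,
    regulons: pd.DataFrame,
    sender: str,
    receiver: str,
) -> list[CommScorePair]:
    """Score every LR pair (with both genes in the universe) for one
    sender->receiver cell-type pair."""
    out = []
    for row in lr_pairs.itertuples(index=False):
        if row.ligand not in ev.gene_pos or row.receptor not in ev.gene_pos:
            continue
        out.append(
            score_pair(ev, row.ligand, row.receptor, sender, receiver,
                       receptor_tf, regulons)
        )
    return out


def significant_pairs(
    pairs: list[CommScorePair], threshold: float = 0.8
) -> list[CommScorePair]:
    """Pairs with both scores at or above the threshold (inclusive)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return [p for p in pairs if p.s_inter >= threshold and p.s_intra >= threshold]


def shared_processes(
    sig_pairs_a: list[CommScorePair],
    sig_pairs_b: list[CommScorePair],
    gene_sets: dict[str, tuple[str, list[str]]],
    universe: set[str],
    alpha: float = 0.05,
    adjusted: bool = False,
) -> list[str]:
    """Process sets enriched (nominal p < alpha by default) in the downstream
    target genes of *both* cohorts' significant pairs.

    ``universe`` should be the regulon-target universe restricted to the
    expression universe.  Returns the sorted intersection of significant set
    ids; empty (with a warning) when a cohort has no significant pairs.
    """
    sig_ids = []
    for label, pairs in (("A", sig_pairs_a), ("B", sig_pairs_b)):
        if not pairs:
            warnings.warn(f"cohort {label}: no significant communication pairs")
            return []
        targets = set()
        for p in pairs:
            targets |= set(p.target_genes)
        targets &= universe
        res = ora(targets, universe, gene_sets, min_hits=1)
        pcol = "p_adj" if adjusted else "p"
        sig_ids.append(set(res.loc[res[pcol] < alpha, "set_id"]))
    return sorted(sig_ids[0] & sig_ids[1])


def pairs_table(pairs: list[CommScorePair]) -> pd.DataFrame:
    rows = [
        {
            "sender": p.sender,
            "receiver": p.receiver,
            "ligand": p.ligand,
            "receptor": p.receptor,
            "s_inter": p.s_inter,
            "s_intra": p.s_intra,
            "best_tf": p.best_tf or "",
            "target_genes": ",".join(p.target_genes),
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sender", "receiver", "ligand", "receptor", "s_inter", "s_intra",
            "best_tf", "target_genes",
        ],
    )
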