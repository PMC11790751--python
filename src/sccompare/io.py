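"""Readers and writers for count bundles and prior-knowledge tables.

A *count bundle* is the on-disk unit of one cohort: a sparse genes x cells
integer count matrix in MatrixMarket format plus two TSV sidecars
(``genes.tsv``: gene id, symbol; ``cells.tsv``: cell id, donor, condition and,
when known, the true cell type). Prior knowledge travels as GMT gene sets and
headered TSV edge/pair tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

CONDITIONS = ("disease", "control")


@dataclass
class CountBundle:
    """Genes x cells integer counts with per-gene and per-cell metadata.

    ``genes`` must carry columns ``gene_id`` and ``symbol``; ``cells`` must
    carry ``cell_id``, ``donor`` and ``condition`` (one of ``disease`` /
    ``control``) and may carry ``cell_type``.
    """

    counts: sp.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        for col in ("gene_id", "symbol"):
            if col not in self.genes.columns:
                raise ValueError(f"genes table missing column {col!r}")
        for col in ("cell_id", "donor", "condition"):
            if col not in self.cells.columns:
                raise ValueError(f"cells table missing column {col!r}")
        bad = set(self.cells["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.genes["gene_id"].to_numpy()

    def subset_cells(self, mask: np.ndarray) -> "CountBundle":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountBundle(
            counts=self.counts[:, idx],
            genes=self.genes,
            cells=self.cells.iloc[idx].reset_index(drop=True),
        )

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        scipy.io.mmwrite(
            os.path.join(outdir, "matrix.mtx"),
            sp.coo_matrix(self.counts.astype(np.int64)),
            field="integer",
        )
        self.genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
        self.cells.to_csv(os.path.join(outdir, "cells.tsv"), sep="\t", index=False)

    @classmethod
    def read(cls, indir: str) -> "CountBundle":
        counts = sp.csr_matrix(scipy.io.mmread(os.path.join(indir, "matrix.mtx")))
        genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t")
        cells = pd.read_csv(os.path.join(indir, "cells.tsv"), sep="\t")
        return cls(counts=counts, genes=genes, cells=cells)


def write_gmt(gene_sets: dict[str, tuple[str, list[str]]], path: str) -> None:
    """Write gene sets as GMT: ``set_id<TAB>description<TAB>member...`` (no header)."""
    with open(path, "w") as fh:
        for set_id, (desc, members) in gene_sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def read_gmt(path: str) -> dict[str, tuple[str, list[str]]]:
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = (parts[1], parts[2:])
    return out


def read_signed_edges(path: str) -> pd.DataFrame:
    """Read ``regulator<TAB>target<TAB>sign`` with header; sign in {+1,-1}."""
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    df["sign"] = df["sign"].astype(int)
    bad = set(df["sign"]) - {1, -1}
    if bad:
        raise ValueError(f"edge signs must be +1/-1, got {sorted(bad)}")
    return df


def read_table(path: str, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


@dataclass
class PriorTables:
    """Prior knowledge consumed by enrichment, GRN and communication stages."""

    gene_sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)  # regulator,target,sign
    lr_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)  # ligand,receptor
    receptor_tf: pd.DataFrame = field(default_factory=pd.DataFrame)  # receptor,tf
    regulons: pd.DataFrame = field(default_factory=pd.DataFrame)  # tf,target
    markers: pd.DataFrame = field(default_factory=pd.DataFrame)  # cell_type,gene

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_gmt(self.gene_sets, os.path.join(outdir, "gene_sets.gmt"))
        self.edges.to_csv(os.path.join(outdir, "edges.tsv"), sep="\t", index=False)
        self.lr_pairs.to_csv(os.path.join(outdir, "lr.tsv"), sep="\t", index=False)
        self.receptor_tf.to_csv(
            os.path.join(outdir, "receptor_tf.tsv"), sep="\t", index=False
        )
        self.regulons.to_csv(os.path.join(outdir, "regulons.tsv"), sep="\t", index=False)
        self.markers.to_csv(os.path.join(outdir, "markers.tsv"), sep="\t", index=False)

    @classmethod
    def read(cls, indir: str) -> "PriorTables":
        return cls(
            gene_sets=read_gmt(os.path.join(indir, "gene_sets.gmt")),
            edges=read_signed_edges(os.path.join(indir, "edges.tsv")),
            lr_pairs=read_table(os.path.join(indir, "lr.tsv"), ("ligand", "receptor")),
            receptor_tf=read_table(
                os.path.join(indir, "receptor_tf.tsv"), ("receptor", "tf")
            ),
            regulons=read_table(os.path.join(indir, "regulons.tsv"), ("tf", "target")),
            markers=read_table(os.path.join(indir, "markers.tsv"), ("cell_type", "gene")),
        )
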