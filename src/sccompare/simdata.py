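"""Paired two-cohort scRNA-seq simulator with planted ground truth.

Generates two disease-vs-control cohorts (``A`` and ``B``) over a shared gene
universe, with negative-binomial counts (gamma-Poisson mixture), marker-defined
cell types, and planted differential-expression signal in five cross-disease
categories:

* ``shared_up`` / ``shared_down`` — same-sign log2 effect in both cohorts,
* ``specific_A`` / ``specific_B`` — effect in one cohort, exactly null in the
  other,
* ``contrasting`` — opposite-sign effects.

Alongside the counts it emits the matching prior-knowledge tables (gene sets,
signed regulator edges, ligand-receptor channels with receptor->TF->regulon
wiring) and a :class:`GroundTruth` record, so every downstream stage of the
pipeline has a known answer to recover.

Effects act multiplicatively on the NB mean: a planted log2 effect ``e``
multiplies the mean by ``2**e`` in disease cells of the stated cell type, which
is exact on means and approximate on normalized-data log fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountBundle, PriorTables

CATEGORIES = ("shared_up", "shared_down", "specific_A", "specific_B", "contrasting")

# mean cap guarding against overflow in the gamma-Poisson draw
_MAX_MEAN = 1e12


@dataclass(frozen=True)
class PlantedDEG:
    gene: int  # gene index in the universe
    cell_type: int  # cell-type index
    category: str
    effect: float  # log2 effect size (magnitude; sign conventions per category)


@dataclass(frozen=True)
class LRChannel:
    """One ligand-receptor communication channel with intracellular wiring."""

    ligand: int
    receptor: int
    sender: int  # sender cell-type index
    receiver: int  # receiver cell-type index
    active_in: str  # one of {"A", "B", "both", "none"}
    tf: int
    targets: tuple[int, ...]


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 2000
    n_cell_types: int = 2
    cells_per_donor: int = 200
    donors_per_condition: int = 2
    baseline_mean: float = 2.0
    nb_dispersion: float = 2.0  # gamma shape; var = mu + mu^2/dispersion
    n_markers_per_type: int = 10
    marker_fold: float = 8.0
    planted_degs: tuple[PlantedDEG, ...] = ()
    n_gene_sets: int = 20  # decoy sets
    set_size: int = 20
    n_activating_edges: int = 150
    n_inhibiting_edges: int = 150
    lr_channels: tuple[LRChannel, ...] = ()
    lr_fold: float = 20.0
    donor_effect_sd: float = 0.0  # lognormal sd of per-donor factor; 0 disables
    seed: int = 0

    def marker_genes(self) -> dict[int, list[int]]:
        """Disjoint marker blocks: type ``t`` owns genes
        ``[t*n_markers_per_type, (t+1)*n_markers_per_type)``."""
        m = self.n_markers_per_type
        return {t: list(range(t * m, (t + 1) * m)) for t in range(self.n_cell_types)}

    def validate(self) -> None:
        for name in (
            "n_genes",
            "n_cell_types",
            "cells_per_donor",
            "donors_per_condition",
            "n_markers_per_type",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("baseline_mean and nb_dispersion must be positive")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        if self.set_size > self.n_genes:
            raise ValueError("set_size cannot exceed n_genes")
        if self.n_cell_types * self.n_markers_per_type > self.n_genes:
            raise ValueError("marker blocks exceed the gene universe")
        marker_set = {g for gs in self.marker_genes().values() for g in gs}
        max_effect = 0.0
        for d in self.planted_degs:
            if d.category not in CATEGORIES:
                raise ValueError(f"unrecognized DEG category {d.category!r}")
            if d.effect == 0:
                raise ValueError(f"planted DEG {d.gene} has zero effect size")
            if d.gene in marker_set:
                raise ValueError(f"planted DEG {d.gene} is a marker gene")
            if not (0 <= d.gene < self.n_genes) or not (
                0 <= d.cell_type < self.n_cell_types
            ):
                raise ValueError(f"planted DEG {d.gene} out of range")
            max_effect = max(max_effect, abs(d.effect))
        seen: dict[tuple[int, int], str] = {}
        for d in self.planted_degs:
            key = (d.gene, d.cell_type)
            if key in seen:
                raise ValueError(f"gene {d.gene} planted twice in cell type {d.cell_type}")
            seen[key] = d.category
        for ch in self.lr_channels:
            if ch.active_in not in ("A", "B", "both", "none"):
                raise ValueError(f"unknown active_in {ch.active_in!r}")
        peak = self.baseline_mean * self.marker_fold * self.lr_fold * 2.0**max_effect
        if peak > _MAX_MEAN:
            raise ValueError(
                f"configured effects push the NB mean to {peak:.3g}, above the "
                f"supported maximum {_MAX_MEAN:.0e}"
            )

    def gene_names(self) -> np.ndarray:
        return np.array([f"G{i:05d}" for i in range(self.n_genes)])

    def type_names(self) -> list[str]:
        return [f"type_{t}" for t in range(self.n_cell_types)]


@dataclass
class GroundTruth:
    """Everything the simulator planted, in recoverable tabular form."""

    cell_types: dict[str, np.ndarray] = field(default_factory=dict)  # cohort -> labels
    categories: pd.DataFrame = field(default_factory=pd.DataFrame)
    # per-cohort true DEG table: cohort, gene, cell_type, direction (+1/-1), log2 effect
    deg_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    markers: dict[str, list[str]] = field(default_factory=dict)
    true_set_ids: list[str] = field(default_factory=list)
    channels: pd.DataFrame = field(default_factory=pd.DataFrame)
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)
    master_regulator: str | None = None

    def write(self, outdir: str) -> None:
        import json
        import os

        os.makedirs(outdir, exist_ok=True)
        self.categories.to_csv(
            os.path.join(outdir, "truth_categories.tsv"), sep="\t", index=False
        )
        self.deg_table.to_csv(
            os.path.join(outdir, "truth_degs.tsv"), sep="\t", index=False
        )
        self.channels.to_csv(
            os.path.join(outdir, "truth_channels.tsv"), sep="\t", index=False
        )
        with open(os.path.join(outdir, "truth_meta.json"), "w") as fh:
            json.dump(
                {
                    "true_set_ids": self.true_set_ids,
                    "master_regulator": self.master_regulator,
                    "markers": self.markers,
                },
                fh,
                indent=1,
            )


def _cohort_effects(deg: PlantedDEG) -> tuple[float, float]:
    """Per-cohort log2 effects implied by the category."""
    e = deg.effect
    if deg.category == "shared_up":
        return abs(e), abs(e)
    if deg.category == "shared_down":
        return -abs(e), -abs(e)
    if deg.category == "specific_A":
        return e, 0.0
    if deg.category == "specific_B":
        return 0.0, e
    if deg.category == "contrasting":
        return e, -e
    raise ValueError(f"unrecognized category {deg.category!r}")


def _cell_layout(config: SimConfig, cohort: str) -> pd.DataFrame:
    """Donor/condition/cell-type layout; types assigned round-robin."""
    rows = []
    i = 0
    for cond in ("disease", "control"):
        for d in range(config.donors_per_condition):
            donor = f"{cohort}_{cond}_donor{d}"
            for c in range(config.cells_per_donor):
                rows.append(
                    {
                        "cell_id": f"{cohort}_cell{i:06d}",
                        "donor": donor,
                        "condition": cond,
                        "cell_type": f"type_{c % config.n_cell_types}",
                    }
                )
                i += 1
    return pd.DataFrame(rows)


def _mean_matrix(config: SimConfig, cohort: str, cells: pd.DataFrame) -> np.ndarray:
    """Dense per-(gene, cell) NB mean implied by markers, planted DEGs and
    active LR channels."""
    n_cells = len(cells)
    mean = np.full((config.n_genes, n_cells), config.baseline_mean)
    type_idx = cells["cell_type"].str.removeprefix("type_").astype(int).to_numpy()
    disease = (cells["condition"] == "disease").to_numpy()

    for t, genes in config.marker_genes().items():
        mean[np.ix_(genes, type_idx == t)] *= config.marker_fold

    which = 0 if cohort == "A" else 1
    for deg in config.planted_degs:
        eff = _cohort_effects(deg)[which]
        if eff != 0.0:
            cols = (type_idx == deg.cell_type) & disease
            mean[deg.gene, cols] *= 2.0**eff

    for ch in config.lr_channels:
        if ch.active_in not in ("both", cohort):
            continue
        mean[ch.ligand, type_idx == ch.sender] *= config.lr_fold
        recv = type_idx == ch.receiver
        for g in (ch.receptor, ch.tf, *ch.targets):
            mean[g, recv] *= config.lr_fold
    return mean


def generate_cohort(
    config: SimConfig, cohort_label: str
) -> tuple[CountBundle, GroundTruth]:
    """Draw one cohort's counts; deterministic given ``config.seed``."""
    if cohort_label not in ("A", "B"):
        raise ValueError("cohort_label must be 'A' or 'B'")
    config.validate()
    rng = np.random.default_rng([config.seed % 2**31, 0 if cohort_label == "A" else 1])
    cells = _cell_layout(config, cohort_label)
    mean = _mean_matrix(config, cohort_label, cells)

    if config.donor_effect_sd > 0:
        donors = cells["donor"].to_numpy()
        factors = {
            d: float(rng.lognormal(0.0, config.donor_effect_sd))
            for d in pd.unique(donors)
        }
        mean = mean * np.array([factors[d] for d in donors])[None, :]

    theta = config.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mean / theta)
    counts = rng.poisson(lam).astype(np.int32)

    gene_names = config.gene_names()
    genes = pd.DataFrame({"gene_id": gene_names, "symbol": gene_names})
    bundle = CountBundle(counts=sp.csr_matrix(counts), genes=genes, cells=cells)
    truth = _ground_truth(config, {cohort_label: cells["cell_type"].to_numpy()})
    return bundle, truth


def _ground_truth(config: SimConfig, cell_types: dict[str, np.ndarray]) -> GroundTruth:
    names = config.gene_names()
    tnames = config.type_names()
    cat_rows, deg_rows = [], []
    for d in config.planted_degs:
        eff_a, eff_b = _cohort_effects(d)
        cat_rows.append(
            {
                "gene": names[d.gene],
                "cell_type": tnames[d.cell_type],
                "category": d.category,
                "effect": d.effect,
            }
        )
        for cohort, eff in (("A", eff_a), ("B", eff_b)):
            if eff != 0.0:
                deg_rows.append(
                    {
                        "cohort": cohort,
                        "gene": names[d.gene],
                        "cell_type": tnames[d.cell_type],
                        "direction": int(np.sign(eff)),
                        "effect": eff,
                    }
                )
    chan_rows = [
        {
            "ligand": names[ch.ligand],
            "receptor": names[ch.receptor],
            "sender": tnames[ch.sender],
            "receiver": tnames[ch.receiver],
            "active_in": ch.active_in,
            "tf": names[ch.tf],
            "targets": ",".join(names[list(ch.targets)]),
        }
        for ch in config.lr_channels
    ]
    return GroundTruth(
        cell_types=cell_types,
        categories=pd.DataFrame(
            cat_rows, columns=["gene", "cell_type", "category", "effect"]
        ),
        deg_table=pd.DataFrame(
            deg_rows, columns=["cohort", "gene", "cell_type", "direction", "effect"]
        ),
        markers={
            tnames[t]: list(names[gs]) for t, gs in config.marker_genes().items()
        },
        channels=pd.DataFrame(
            chan_rows,
            columns=[
                "ligand",
                "receptor",
                "sender",
                "receiver",
                "active_in",
                "tf",
                "targets",
            ],
        ),
    )


def generate_paired_cohorts(
    config: SimConfig,
) -> tuple[CountBundle, CountBundle, GroundTruth]:
    """Both cohorts over the shared universe, plus the combined ground truth."""
    bundle_a, _ = generate_cohort(config, "A")
    bundle_b, _ = generate_cohort(config, "B")
    truth = _ground_truth(
        config,
        {
            "A": bundle_a.cells["cell_type"].to_numpy(),
            "B": bundle_b.cells["cell_type"].to_numpy(),
        },
    )
    return bundle_a, bundle_b, truth


def generate_priors(config: SimConfig, truth: GroundTruth) -> PriorTables:
    """Prior-knowledge tables matched to the planted signal, plus decoys.

    True gene sets carry the planted DEGs of one category (padded with
    background genes); one set per LR channel carries its regulon targets;
    decoy sets are uniform draws from the universe.  The signed edge list puts
    one master regulator upstream of every shared planted DEG with
    sign-consistent edges, plus random activating/inhibiting decoy edges.
    """
    config.validate()
    rng = np.random.default_rng([config.seed % 2**31, 2])
    names = config.gene_names()
    name_list = list(names)
    marker_set = {g for gs in config.marker_genes().values() for g in gs}
    planted_idx = {d.gene for d in config.planted_degs}
    channel_idx = {
        g
        for ch in config.lr_channels
        for g in (ch.ligand, ch.receptor, ch.tf, *ch.targets)
    }
    reserved = marker_set | planted_idx | channel_idx
    background = np.array(sorted(set(range(config.n_genes)) - reserved))

    gene_sets: dict[str, tuple[str, list[str]]] = {}
    true_ids: list[str] = []
    if len(truth.categories):
        for cat, sub in truth.categories.groupby("category"):
            members = list(sub["gene"].unique())
            pad = config.set_size - len(members)
            if pad > 0 and len(background):
                members = members + list(
                    names[rng.choice(background, size=min(pad, len(background)), replace=False)]
                )
            sid = f"true_{cat}"
            gene_sets[sid] = (f"planted {cat} set", members)
            true_ids.append(sid)
    for i, ch in enumerate(config.lr_channels):
        members = list(names[list(ch.targets)])
        pad = config.set_size - len(members)
        if pad > 0 and len(background):
            members = members + list(
                names[rng.choice(background, size=min(pad, len(background)), replace=False)]
            )
        gene_sets[f"true_lr_{i}"] = (f"targets of LR channel {i}", members)
    for i in range(config.n_gene_sets):
        members = list(
            names[rng.choice(config.n_genes, size=config.set_size, replace=False)]
        )
        gene_sets[f"decoy_{i:03d}"] = ("decoy set", members)

    edge_rows = []
    master: str | None = None
    if len(truth.categories):
        shared = truth.categories[
            truth.categories["category"].isin(["shared_up", "shared_down"])
        ]
    else:
        shared = pd.DataFrame(columns=["gene", "category"])
    if len(shared) and len(background):
        master_idx = int(background[0])
        master = name_list[master_idx]
        for _, row in shared.iterrows():
            sign = 1 if row["category"] == "shared_up" else -1
            edge_rows.append(
                {"regulator": master, "target": row["gene"], "sign": sign}
            )
    n_decoy = config.n_activating_edges + config.n_inhibiting_edges
    signs = np.array([1] * config.n_activating_edges + [-1] * config.n_inhibiting_edges)
    seen_pairs = {(r["regulator"], r["target"]) for r in edge_rows}
    made = 0
    while made < n_decoy:
        u, v = rng.integers(0, config.n_genes, size=2)
        pair = (name_list[u], name_list[v])
        if u == v or pair in seen_pairs or pair[0] == master:
            continue
        seen_pairs.add(pair)
        edge_rows.append(
            {"regulator": pair[0], "target": pair[1], "sign": int(signs[made])}
        )
        made += 1
    edges = pd.DataFrame(edge_rows, columns=["regulator", "target", "sign"])

    lr = pd.DataFrame(
        {
            "ligand": [names[ch.ligand] for ch in config.lr_channels],
            "receptor": [names[ch.receptor] for ch in config.lr_channels],
        }
    )
    receptor_tf = pd.DataFrame(
        {
            "receptor": [names[ch.receptor] for ch in config.lr_channels],
            "tf": [names[ch.tf] for ch in config.lr_channels],
        }
    )
    regulon_rows = [
        {"tf": names[ch.tf], "target": names[t]}
        for ch in config.lr_channels
        for t in ch.targets
    ]
    regulons = pd.DataFrame(regulon_rows, columns=["tf", "target"])
    marker_rows = [
        {"cell_type": ct, "gene": g} for ct, gs in truth.markers.items() for g in gs
    ]
    markers = pd.DataFrame(marker_rows, columns=["cell_type", "gene"])

    truth.true_set_ids = true_ids
    truth.edges = edges
    truth.master_regulator = master
    return PriorTables(
        gene_sets=gene_sets,
        edges=edges,
        lr_pairs=lr,
        receptor_tf=receptor_tf,
        regulons=regulons,
        markers=markers,
    )


def default_channels(config_like: SimConfig | None = None) -> tuple[LRChannel, ...]:
    """Four canonical channels (active in both / A only / B only / none) from
    type_0 senders to type_1 receivers, on reserved background genes."""
    base = 1500  # keep clear of marker and planted blocks under defaults
    channels = []
    for i, active in enumerate(["both", "A", "B", "none"]):
        g = base + i * 8
        channels.append(
            LRChannel(
                ligand=g,
                receptor=g + 1,
                sender=0,
                receiver=1,
                active_in=active,
                tf=g + 2,
                targets=tuple(range(g + 3, g + 8)),
            )
        )
    return tuple(channels)


def default_config(seed: int = 0, with_channels: bool = True) -> SimConfig:
    """The study-condition configuration: 10 planted genes per category at
    |log2 effect| 1.5, 200 cells per group per cell type, NB baseline mean 2."""
    planted = []
    g = 100  # planted block starts after the marker blocks
    for cat in CATEGORIES:
        for _ in range(10):
            planted.append(PlantedDEG(gene=g, cell_type=0, category=cat, effect=1.5))
            g += 1
    cfg = SimConfig(planted_degs=tuple(planted), seed=seed)
    if with_channels:
        cfg = replace(cfg, lr_channels=default_channels())
    return cfg


def null_config(seed: int = 0, n_genes: int = 2000, cells_per_donor: int = 50) -> SimConfig:
    """No planted effects: disease and control exchangeable per gene."""
    return SimConfig(
        n_genes=n_genes,
        n_cell_types=1,
        cells_per_donor=cells_per_donor,
        donors_per_condition=1,
        planted_degs=(),
        lr_channels=(),
        seed=seed,
    )
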