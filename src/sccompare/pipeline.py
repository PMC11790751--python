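"""End-to-end orchestration: two cohort bundles in, comparison tables out.

``run_all`` drives preprocess -> per-cohort, per-cell-type DE -> cross-disease
classification -> directional enrichment -> signed-network perturbagen
ranking -> ligand-receptor communication comparison, writing each stage's TSV
outputs and a JSON manifest (seeds, input digests, per-stage row counts).
Reruns with the same config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import ccc, crossdisease, degtest, enrich, grn, preprocess, simdata
from .io import CountBundle, PriorTables

log = logging.getLogger("sccompare")

SHARED = ("shared_up", "shared_down")
ENRICH_CATEGORIES = ("shared", "contrasting")


@dataclass
class RunConfig:
    cohort_a: str
    cohort_b: str
    priors: str
    outdir: str
    qc: preprocess.QCParams = field(default_factory=preprocess.QCParams)
    n_hvg: int = 3000
    max_pcs: int = 17
    n_pcs: int | None = None
    resolution_grid: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6)
    knn: int = 20
    thresholds: crossdisease.Thresholds = field(default_factory=crossdisease.Thresholds)
    ora_min_hits: int = 6
    comm_threshold: float = 0.8
    min_cells_per_type: int = 50
    merge_map: dict[str, str] = field(default_factory=dict)
    ccc_pairs: list[tuple[str, str]] | str = "all"
    seed: int = 0

    def validate(self) -> None:
        for path in (self.cohort_a, self.cohort_b, self.priors):
            if not os.path.isdir(path):
                raise FileNotFoundError(f"input directory not found: {path}")
            for fname in ("matrix.mtx", "genes.tsv", "cells.tsv"):
                if path != self.priors and not os.path.exists(
                    os.path.join(path, fname)
                ):
                    raise FileNotFoundError(f"missing {fname} in {path}")
        for fname in ("gene_sets.gmt", "edges.tsv", "lr.tsv", "receptor_tf.tsv",
                      "regulons.tsv", "markers.tsv"):
            if not os.path.exists(os.path.join(self.priors, fname)):
                raise FileNotFoundError(f"missing prior file {fname} in {self.priors}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            qc = preprocess.QCParams(**raw.pop("qc", {}))
            thr = crossdisease.Thresholds(**raw.pop("thresholds", {}))
            grid = tuple(raw.pop("resolution_grid", (0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6)))
            pairs = raw.pop("ccc_pairs", "all")
            if isinstance(pairs, list):
                pairs = [tuple(p) for p in pairs]
            return cls(qc=qc, thresholds=thr, resolution_grid=grid,
                       ccc_pairs=pairs, **raw)
        except TypeError as exc:
            raise ValueError(f"malformed run config {path}: {exc}") from exc


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _input_digests(config: RunConfig) -> dict[str, str]:
    out = {}
    for root in (config.cohort_a, config.cohort_b, config.priors):
        for fname in sorted(os.listdir(root)):
            fpath = os.path.join(root, fname)
            if os.path.isfile(fpath):
                out[os.path.relpath(fpath, start=os.path.dirname(root) or ".")] = _digest(fpath)
    return out


def preprocess_cohort(
    bundle: CountBundle, priors: PriorTables, config: RunConfig, cohort: str
) -> tuple[preprocess.NormalizedData, np.ndarray, dict]:
    """QC -> normalize/HVG -> PCA -> Louvain/silhouette -> annotate -> merge.

    Returns (normalized data, per-cell type labels, report dict); the bundle
    is QC-filtered in place of the caller's copy.
    """
    filtered = preprocess.qc_filter(bundle, config.qc)
    norm = preprocess.normalize_and_select_hvg(filtered, n_hvg=config.n_hvg)
    k, scores = preprocess.select_pcs_elbow(
        norm.hvg_matrix, max_pcs=config.max_pcs, n_pcs=config.n_pcs
    )
    best, solutions = preprocess.cluster_with_silhouette(
        scores, resolution_grid=config.resolution_grid, knn=config.knn,
        seed=config.seed,
    )
    ann = preprocess.annotate_clusters(
        norm.matrix, norm.gene_ids, best.labels, priors.markers
    )
    if config.merge_map:
        ann = preprocess.merge_labels(ann, config.merge_map)
    report = {
        "cohort": cohort,
        "n_cells_in": int(bundle.n_cells),
        "n_cells_kept": int(filtered.n_cells),
        "n_pcs": int(k),
        "best_resolution": best.resolution,
        "solutions": [
            {"resolution": s.resolution, "n_clusters": s.n_clusters,
             "mean_silhouette": s.mean_silhouette}
            for s in solutions
        ],
        "cluster_labels": {
            str(r["cluster"]): r["cell_type"]
            for _, r in ann.assignments.iterrows()
        },
    }
    return norm, ann.cell_labels, {"filtered": filtered, "report": report,
                                   "clusters": best.labels}


def _eligible_cell_types(
    labels_by_key: dict[str, np.ndarray],
    conditions_by_key: dict[str, np.ndarray],
    min_cells: int,
) -> list[str]:
    """Cell types with enough cells in both conditions of both cohorts."""
    common: set[str] | None = None
    for key, labels in labels_by_key.items():
        cond = conditions_by_key[key]
        ok = set()
        for ct in np.unique(labels):
            if ct == "unknown":
                continue
            if ((labels == ct) & (cond == "disease")).sum() >= min_cells and (
                (labels == ct) & (cond == "control")
            ).sum() >= min_cells:
                ok.add(str(ct))
        common = ok if common is None else (common & ok)
    return sorted(common or ())


def run_all(config: RunConfig) -> dict:
    """Execute the full comparison; returns the manifest (also written to
    ``manifest.json``).  A stage failure is recorded and downstream stages are
    skipped."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "input_digests": _input_digests(config),
        "stages": {},
    }
    state: dict = {}
    try:
        _stage_preprocess(config, state, manifest)
        _stage_de(config, state, manifest)
        _stage_crossdisease(config, state, manifest)
        _stage_enrich(config, state, manifest)
        _stage_grn(config, state, manifest)
        _stage_ccc(config, state, manifest)
    except Exception as exc:  # manifest records the failing stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        log.exception("pipeline failed")
        raise
    finally:
        with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _stage_preprocess(config: RunConfig, state: dict, manifest: dict) -> None:
    manifest["stages"]["preprocess"] = {"status": "running"}
    priors = PriorTables.read(config.priors)
    state["priors"] = priors
    for cohort, path in (("A", config.cohort_a), ("B", config.cohort_b)):
        bundle = CountBundle.read(path)
        norm, labels, extra = preprocess_cohort(bundle, priors, config, cohort)
        state[f"norm_{cohort}"] = norm
        state[f"labels_{cohort}"] = labels
        state[f"cells_{cohort}"] = extra["filtered"].cells
        out = extra["filtered"].cells[["cell_id", "donor", "condition"]].copy()
        out["cluster"] = extra["clusters"]
        out["label"] = labels
        out.to_csv(
            os.path.join(config.outdir, f"cells_annotated_{cohort}.tsv"),
            sep="\t", index=False,
        )
        with open(
            os.path.join(config.outdir, f"cluster_report_{cohort}.json"), "w"
        ) as fh:
            json.dump(extra["report"], fh, indent=1)
    manifest["stages"]["preprocess"] = {
        "status": "done",
        "cells": {c: int(len(state[f"cells_{c}"])) for c in ("A", "B")},
    }


def _stage_de(config: RunConfig, state: dict, manifest: dict) -> None:
    manifest["stages"]["de"] = {"status": "running"}
    cell_types = _eligible_cell_types(
        {c: state[f"labels_{c}"] for c in ("A", "B")},
        {c: state[f"cells_{c}"]["condition"].to_numpy() for c in ("A", "B")},
        config.min_cells_per_type,
    )
    state["cell_types"] = cell_types
    degs: dict[str, list[pd.DataFrame]] = {"A": [], "B": []}
    for cohort in ("A", "B"):
        norm = state[f"norm_{cohort}"]
        conditions = state[f"cells_{cohort}"]["condition"].to_numpy()
        for ct in cell_types:
            table = degtest.run_de(
                norm.matrix, norm.gene_ids, conditions,
                state[f"labels_{cohort}"], ct,
            )
            table.to_csv(
                os.path.join(config.outdir, f"degs_{cohort}_{ct}.tsv"),
                sep="\t", index=False,
            )
            degs[cohort].append(table)
    state["degs"] = {
        c: pd.concat(v, ignore_index=True) if v else pd.DataFrame(
            columns=["gene", "cell_type", "log2fc", "p_nominal", "fdr",
                     "pct_disease", "pct_control"]
        )
        for c, v in degs.items()
    }
    manifest["stages"]["de"] = {
        "status": "done",
        "cell_types": cell_types,
        "tested": {c: int(len(state["degs"][c])) for c in ("A", "B")},
    }


def _stage_crossdisease(config: RunConfig, state: dict, manifest: dict) -> None:
    manifest["stages"]["crossdisease"] = {"status": "running"}
    calls = crossdisease.classify_table(
        state["degs"]["A"], state["degs"]["B"], config.thresholds
    )
    calls.to_csv(
        os.path.join(config.outdir, "cross_disease_calls.tsv"), sep="\t", index=False
    )
    venn = crossdisease.venn_counts(calls)
    fisher = {}
    for ct in state.get("cell_types", []):
        sub = calls[calls["cell_type"] == ct]
        if len(sub):
            fisher[ct] = crossdisease.overlap_test(sub, config.thresholds)
    with open(os.path.join(config.outdir, "venn_counts.json"), "w") as fh:
        json.dump(
            {"per_cell_type": venn.to_dict(orient="records"),
             "fisher_overlap_p": fisher},
            fh, indent=1,
        )
    state["calls"] = calls
    manifest["stages"]["crossdisease"] = {
        "status": "done", "classified": int(len(calls)),
    }


def _category_genes(calls: pd.DataFrame, category: str) -> pd.DataFrame:
    if category == "shared":
        return calls[calls["category"].isin(SHARED)]
    return calls[calls["category"] == category]


def _stage_enrich(config: RunConfig, state: dict, manifest: dict) -> None:
    manifest["stages"]["enrich"] = {"status": "running"}
    counts = {}
    for ct in state.get("cell_types", []):
        sub = state["calls"][
            (state["calls"]["cell_type"] == ct)
            & (state["calls"]["reason"] != "untested_in_one_cohort")
        ]
        universe = set(sub["gene"])
        if not universe:
            continue
        for category in ENRICH_CATEGORIES:
            cat_calls = _category_genes(sub, category)
            res_calls = sub.copy()
            res_calls["category"] = np.where(
                res_calls.index.isin(cat_calls.index), category, "other"
            )
            res = enrich.enrich_category(
                res_calls, category, universe, state["priors"].gene_sets,
                min_hits=config.ora_min_hits,
            )
            res.to_csv(
                os.path.join(config.outdir, f"enrichment_{ct}_{category}.tsv"),
                sep="\t", index=False,
            )
            counts[f"{ct}:{category}"] = int(res["significant"].sum()) if len(res) else 0
    manifest["stages"]["enrich"] = {"status": "done", "significant_sets": counts}


def _stage_grn(config: RunConfig, state: dict, manifest: dict) -> None:
    manifest["stages"]["grn"] = {"status": "running"}
    info = {}
    for ct in state.get("cell_types", []):
        sub = state["calls"][state["calls"]["cell_type"] == ct]
        for category in ENRICH_CATEGORIES:
            cat_calls = _category_genes(sub, category)
            genes = set(cat_calls["gene"])
            key = f"{ct}:{category}"
            if not genes:
                info[key] = {"nodes": 0, "edges": 0}
                continue
            signs = {
                row.gene: int(np.sign(row.log2fc_A))
                for row in cat_calls.itertuples(index=False)
                if np.sign(row.log2fc_A) != 0
            }
            try:
                network = grn.build_subnetwork(genes, state["priors"].edges, signs)
            except ValueError:
                info[key] = {"nodes": 0, "edges": 0}
                continue
            if network.is_empty:
                info[key] = {"nodes": 0, "edges": 0}
                continue
            network.edge_table().to_csv(
                os.path.join(config.outdir, f"grn_{ct}_{category}.tsv"),
                sep="\t", index=False,
            )
            hubs = pd.DataFrame(degree_rank_rows(network))
            hubs.to_csv(
                os.path.join(config.outdir, f"hubs_{ct}_{category}.tsv"),
                sep="\t", index=False,
            )
            perts = grn.rank_perturbagens(network)
            perts.to_csv(
                os.path.join(config.outdir, f"perturbagens_{ct}_{category}.tsv"),
                sep="\t", index=False,
            )
            info[key] = {
                "nodes": network.graph.number_of_nodes(),
                "edges": network.graph.number_of_edges(),
                "top_perturbagen": perts["node"].iloc[0] if len(perts) else None,
            }
    manifest["stages"]["grn"] = {"status": "done", "networks": info}


def degree_rank_rows(network: grn.SignedGRN) -> list[dict]:
    return [{"node": n, "degree": d} for n, d in grn.degree_rank(network)]


def _stage_ccc(config: RunConfig, state: dict, manifest: dict) -> None:
    manifest["stages"]["ccc"] = {"status": "running"}
    priors = state["priors"]
    cell_types = state.get("cell_types", [])
    if config.ccc_pairs == "all":
        pairs = [(s, r) for s in cell_types for r in cell_types if s != r]
    else:
        pairs = list(config.ccc_pairs)
    sig_by_cohort: dict[str, list[ccc.CommScorePair]] = {}
    counts = {}
    for cohort in ("A", "B"):
        ev = ccc.ClusterEvidence(
            state[f"norm_{cohort}"].matrix,
            state[f"norm_{cohort}"].gene_ids,
            state[f"labels_{cohort}"],
        )
        scored: list[ccc.CommScorePair] = []
        present = set(np.unique(state[f"labels_{cohort}"]))
        for sender, receiver in pairs:
            if sender not in present or receiver not in present:
                continue
            scored.extend(
                ccc.score_all_pairs(
                    ev, priors.lr_pairs, priors.receptor_tf, priors.regulons,
                    sender, receiver,
                )
            )
        ccc.pairs_table(scored).to_csv(
            os.path.join(config.outdir, f"comm_pairs_{cohort}.tsv"),
            sep="\t", index=False,
        )
        sig = ccc.significant_pairs(scored, threshold=config.comm_threshold)
        sig_by_cohort[cohort] = sig
        counts[cohort] = {"scored": len(scored), "significant": len(sig)}
    expr_universe = set(state["norm_A"].gene_ids) & set(state["norm_B"].gene_ids)
    target_universe = set(priors.regulons["target"]) & expr_universe
    shared: list[str] = []
    if target_universe:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shared = ccc.shared_processes(
                sig_by_cohort["A"], sig_by_cohort["B"], priors.gene_sets,
                target_universe,
            )
    pd.DataFrame({"set_id": shared}).to_csv(
        os.path.join(config.outdir, "shared_processes.tsv"), sep="\t", index=False
    )
    manifest["stages"]["ccc"] = {
        "status": "done", "pairs": counts, "shared_processes": shared,
    }


def simulate_to_dir(sim_config: simdata.SimConfig, outdir: str) -> dict:
    """Write the full simulated fixture tree (both cohorts, priors, truth)."""
    bundle_a, bundle_b, truth = simdata.generate_paired_cohorts(sim_config)
    priors = simdata.generate_priors(sim_config, truth)
    bundle_a.write(os.path.join(outdir, "cohort_A"))
    bundle_b.write(os.path.join(outdir, "cohort_B"))
    priors.write(os.path.join(outdir, "priors"))
    truth.write(os.path.join(outdir, "truth"))
    return {
        "cohort_a": os.path.join(outdir, "cohort_A"),
        "cohort_b": os.path.join(outdir, "cohort_B"),
        "priors": os.path.join(outdir, "priors"),
        "truth": os.path.join(outdir, "truth"),
    }


def sim_config_from_yaml(path: str) -> simdata.SimConfig:
    """Build a :class:`simdata.SimConfig` from a YAML file.

    The ``planted`` block may give ``per_category``/``effect``/``cell_type``
    shorthand instead of explicit gene indices; ``channels: default`` requests
    the four canonical LR channels.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    planted_spec = raw.pop("planted", None)
    channels_spec = raw.pop("channels", None)
    try:
        cfg = simdata.SimConfig(**raw)
    except TypeError as exc:
        raise ValueError(f"malformed sim config {path}: {exc}") from exc
    if planted_spec:
        if "per_category" in planted_spec:
            n_per = int(planted_spec["per_category"])
            effect = float(planted_spec.get("effect", 1.5))
            ct = int(planted_spec.get("cell_type", 0))
            start = int(
                planted_spec.get(
                    "start_gene", cfg.n_cell_types * cfg.n_markers_per_type
                )
            )
            planted, g = [], start
            for cat in simdata.CATEGORIES:
                for _ in range(n_per):
                    planted.append(
                        simdata.PlantedDEG(gene=g, cell_type=ct, category=cat,
                                           effect=effect)
                    )
                    g += 1
        else:
            planted = [simdata.PlantedDEG(**d) for d in planted_spec]
        cfg = replace(cfg, planted_degs=tuple(planted))
    if channels_spec == "default":
        cfg = replace(cfg, lr_channels=simdata.default_channels())
    elif channels_spec:
        cfg = replace(
            cfg,
            lr_channels=tuple(
                simdata.LRChannel(**{**d, "targets": tuple(d["targets"])})
                for d in channels_spec
            ),
        )
    cfg.validate()
    return cfg
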