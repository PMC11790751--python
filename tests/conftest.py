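import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sccompare import simdata
from sccompare.io import CountBundle


@pytest.fixture(scope="session")
def small_config():
    """A fast paired-cohort configuration: 600 genes, 1 cell type, 2 planted
    genes per category at |log2 effect| 1.5, 100 cells per group."""
    planted = []
    g = 20
    for cat in simdata.CATEGORIES:
        for _ in range(2):
            planted.append(
                simdata.PlantedDEG(gene=g, cell_type=0, category=cat, effect=1.5)
            )
            g += 1
    return simdata.SimConfig(
        n_genes=600,
        n_cell_types=1,
        cells_per_donor=100,
        donors_per_condition=1,
        n_markers_per_type=10,
        planted_degs=tuple(planted),
        n_gene_sets=5,
        set_size=10,
        n_activating_edges=30,
        n_inhibiting_edges=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohorts(small_config):
    return simdata.generate_paired_cohorts(small_config)


@pytest.fixture(scope="session")
def study_cohorts():
    """One draw of the default study configuration (2 cell types, 2000 genes,
    200 cells per group per type, LR channels wired)."""
    cfg = simdata.default_config(seed=7)
    a, b, truth = simdata.generate_paired_cohorts(cfg)
    priors = simdata.generate_priors(cfg, truth)
    return cfg, a, b, truth, priors


def make_bundle(counts, symbols=None, conditions=None, cell_types=None):
    """Tiny dense-count bundle helper for unit tests."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    symbols = symbols or [f"g{i}" for i in range(n_genes)]
    genes = pd.DataFrame({"gene_id": symbols, "symbol": symbols})
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "donor": ["d0"] * n_cells,
            "condition": conditions or ["disease"] * n_cells,
        }
    )
    if cell_types is not None:
        cells["cell_type"] = cell_types
    return CountBundle(counts=sp.csr_matrix(counts), genes=genes, cells=cells)
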