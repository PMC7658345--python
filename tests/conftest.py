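import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tamscape.ingest import CountMatrix, NormMatrix, lognormalize
from tamscape.syndata import SynthConfig, generate_single_cell, default_signatures


def make_counts(counts, gene_ids=None, regions=None, tumors=None) -> CountMatrix:
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    meta = pd.DataFrame(
        {
            "region": regions or ["core"] * n_cells,
            "tumor_id": tumors or ["T1"] * n_cells,
        },
        index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id"),
    )
    return CountMatrix(sp.csr_matrix(counts), gene_ids, meta)


def make_norm(values, gene_ids=None) -> NormMatrix:
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    meta = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id"))
    return NormMatrix(values, gene_ids, meta, ["lognorm"])


@pytest.fixture(scope="session")
def syn_small():
    """Shared medium-size synthetic dataset with ground truth."""
    cfg = SynthConfig(n_cells_core=600, n_cells_periphery=300, n_genes=600, seed=11)
    cm, truth = generate_single_cell(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def syn_small_norm(syn_small):
    _, cm, _ = syn_small
    return lognormalize(cm)


@pytest.fixture(scope="session")
def syn_signatures(syn_small):
    _, _, truth = syn_small
    return default_signatures(truth)
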