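import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scptwas.io_formats import CellMatrix
from scptwas.synthetic_data import SimConfig, simulate_all


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return SimConfig(
        n_genes=10, n_individuals=80, snps_per_gene=10, feature_dim=16,
        cells_per_individual=10, gwas_n=400, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_all(tiny_config)


def make_cell_matrix(counts, individual_ids, cell_type="T", n_count_total=None,
                     mito_pct=None) -> CellMatrix:
    """Dense counts (cells x genes) plus minimal metadata."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_ids = [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "individual_id": individual_ids,
            "cell_type": cell_type,
            "n_count_total": counts.sum(axis=1) if n_count_total is None else n_count_total,
            "mito_pct": 5.0 if mito_pct is None else mito_pct,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CellMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=[f"g{j}" for j in range(n_genes)],
        cell_ids=cell_ids,
        cell_meta=meta,
    )
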