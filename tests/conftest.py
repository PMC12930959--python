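import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scdimorph.preprocess import lognormalize
from scdimorph.simulate import SimConfig, generate_cohort


def make_cohort(counts: np.ndarray, cell_types=None, sexes=None, treatments=None,
                is_mito=None) -> ad.AnnData:
    """Hand-built cohort from an explicit cells x genes count matrix."""
    n_cells, n_genes = counts.shape
    obs = pd.DataFrame({
        "sample_id": [f"s{i % 3}" for i in range(n_cells)],
        "sex": sexes if sexes is not None else ["XX"] * n_cells,
        "treatment": treatments if treatments is not None else ["V"] * n_cells,
        "replicate": [i % 3 + 1 for i in range(n_cells)],
        "cell_type": cell_types if cell_types is not None else ["A"] * n_cells,
    }, index=[f"c{i}" for i in range(n_cells)])
    var = pd.DataFrame(
        {"is_mito": is_mito if is_mito is not None else np.zeros(n_genes, bool)},
        index=[f"g{i}" for i in range(n_genes)])
    return ad.AnnData(X=sp.csr_matrix(counts.astype(float)), obs=obs, var=var)


@pytest.fixture(scope="session")
def small_cohort() -> ad.AnnData:
    """Deterministic 2-cell-type cohort without QC-failing cells."""
    return generate_cohort(SimConfig(
        seed=11, cell_types=("A", "B"), cells_per_group=40, n_genes=250,
        mito_gene_fraction=0.0, damaged_cell_fraction=0.0))


@pytest.fixture(scope="session")
def small_norm(small_cohort) -> ad.AnnData:
    return lognormalize(small_cohort)
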