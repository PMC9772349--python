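import numpy as np
import pandas as pd
import pytest

import sncausal as sc


@pytest.fixture(scope="session")
def small_design():
    """Compact design exercising every planted structure."""
    return sc.SyntheticDesign(
        n_genes=400,
        cell_types={"MSN": 80, "OL": 80},
        n_modules=2,
        module_size=30,
        dag_genes=10,
        n_deg=30,
        n_cag_genes=20,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return sc.generate_dataset(small_design)


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    counts, meta, truth = small_dataset
    return sc.log_normalize(counts), meta, truth


def toy_normalized(values, genes=None, barcodes=None):
    """Build a NormalizedMatrix directly from a genes x cells array."""
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    genes = pd.Index(genes if genes is not None else [f"g{i}" for i in range(g)])
    barcodes = pd.Index(
        barcodes if barcodes is not None else [f"c{i}" for i in range(c)]
    )
    return sc.NormalizedMatrix(values, genes, barcodes)
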