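import numpy as np
import pytest
import scipy.sparse as sp

from capblood.io import CountMatrix, empty_annotation
from capblood.simulate import (
    SimConfig,
    design_from_config,
    generate_dataset,
    true_annotation,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_genes=300,
        cells_per_sample=80,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One generated study: (matrix, raw annotation, truth, design)."""
    matrix, ann, truth = generate_dataset(small_config)
    return matrix, ann, truth, design_from_config(small_config)


@pytest.fixture(scope="session")
def small_typed(small_dataset):
    """Same study with ground-truth cell types and debris flags applied."""
    matrix, ann, truth, design = small_dataset
    return matrix, true_annotation(ann, truth), truth, design


def toy_matrix(counts, barcodes=None, genes=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    return CountMatrix(
        sp.csr_matrix(counts),
        barcodes or [f"c{i}" for i in range(n)],
        genes or [f"g{i}" for i in range(g)],
        genes or [f"g{i}" for i in range(g)],
    )


@pytest.fixture
def toy():
    return toy_matrix


@pytest.fixture
def annotation_for():
    def make(matrix, **cols):
        ann = empty_annotation(matrix.barcodes)
        for col, values in cols.items():
            ann.df[col] = np.asarray(values, dtype=object)
            if col == "day":
                ann.df[col] = ann.df[col].astype("Int64")
        return ann

    return make
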