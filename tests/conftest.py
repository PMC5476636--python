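import numpy as np
import pytest

import recat
from recat.preprocess import log_transform, normalize, subset_to_catalog


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic cycle (120 cells, 80 genes) with ground truth."""
    cfg = recat.CycleSimConfig(n_cells=120, n_genes=80, seed=42)
    mat, truth = recat.simulate_expression(cfg)
    return mat, truth


@pytest.fixture(scope="session")
def small_log(small_sim):
    """The small simulation normalized and log2-transformed, catalog genes only."""
    mat, truth = small_sim
    catalog = recat.make_catalog(truth)
    m = subset_to_catalog(log_transform(normalize(mat)), catalog)
    return m, truth, catalog


@pytest.fixture
def toy_matrix():
    """Tiny hand-checkable matrix: 3 genes x 3 cells."""
    values = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [0.0, 1.0, 2.0]])
    return recat.ExpressionMatrix(values, ["g1", "g2", "g3"], ["c1", "c2", "c3"], unit="TPM")
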