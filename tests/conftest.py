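import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import tregdegron as td
from tregdegron.containers import CountMatrix


def dense_counts(arr, cell_prefix="c", gene_prefix="g") -> CountMatrix:
    """Build a CountMatrix from a dense array (rows cells, cols genes)."""
    arr = np.asarray(arr)
    return CountMatrix(
        sp.csr_matrix(arr),
        [f"{cell_prefix}{i}" for i in range(arr.shape[0])],
        [f"{gene_prefix}{j}" for j in range(arr.shape[1])],
    )


@pytest.fixture(scope="session")
def small_config() -> td.SimulationConfig:
    return td.SimulationConfig(
        n_genes=400,
        n_cells_per_group=20,
        module_sizes={
            "direct_activated": 15,
            "direct_repressed": 15,
            "indirect": 20,
            "null": 350,
        },
        seed=20,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return td.make_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_truth):
    counts, cells = td.simulate_cells(small_truth, small_config)
    return counts, cells


@pytest.fixture(scope="session")
def regulatory_truth(small_config, small_truth):
    return td.simulate_regulatory_annotation(small_truth, small_config)
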