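import numpy as np
import pytest
import scipy.sparse as sp

from napctraj import SimulationConfig, UMICountMatrix, simulate_trajectory_counts


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across tests."""
    cfg = SimulationConfig(seed=1)
    counts, hto, truth = simulate_trajectory_counts(cfg)
    return cfg, counts, hto, truth


@pytest.fixture()
def tiny_counts():
    """A hand-sized 4-gene x 3-cell count matrix."""
    mat = sp.csr_matrix(
        np.array(
            [[1, 0, 2],
             [0, 3, 1],
             [5, 0, 0],
             [2, 2, 2]]
        )
    )
    return UMICountMatrix(mat, ["g1", "g2", "mt-g3", "g4"], ["c1", "c2", "c3"])
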