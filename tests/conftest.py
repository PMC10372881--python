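import numpy as np
import pandas as pd
import pytest

from tilseq import hto, simulate


@pytest.fixture(scope="session")
def default_hto_sim():
    """One default hashing array plus its truth table (seed 1)."""
    cfg = simulate.HtoSimConfig(seed=1)
    return simulate.simulate_hto(cfg)


@pytest.fixture(scope="session")
def default_demux(default_hto_sim):
    matrix, truth = default_hto_sim
    result = hto.demux([matrix])[0]
    return result, truth


def make_clr(values: np.ndarray, n_htos: int = 2) -> hto.ClrMatrix:
    """1-D values embedded as a 2-HTO CLR matrix (rows sum to zero)."""
    values = np.asarray(values, dtype=float)
    mat = np.column_stack([values, -values])
    barcodes = [f"c{i}" for i in range(len(values))]
    return hto.ClrMatrix(mat, barcodes, [f"HTO{i+1}" for i in range(n_htos)])


def single_cluster(n: int, dominant: str = "HTO1") -> hto.ClusterAssignment:
    return hto.ClusterAssignment(
        labels=np.zeros(n, dtype=int), medoids=np.array([0]),
        dominant_hto=[dominant], cost=0.0)
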