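import numpy as np
import pandas as pd
import pytest

from coexdiff.design import generate_design
from coexdiff.network import CoexpressionNetwork
from coexdiff.simulate import TruthConfig, simulate_intensities


def net_from_edges(nodes, edges):
    """Build a CoexpressionNetwork from an explicit edge list."""
    pos = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for a, b in edges:
        A[pos[a], pos[b]] = A[pos[b], pos[a]] = True
    return CoexpressionNetwork(list(nodes), A)


def random_network(n_nodes, p, seed):
    """Erdos–Renyi style random symmetric adjacency (test helper)."""
    rng = np.random.default_rng(seed)
    A = rng.random((n_nodes, n_nodes)) < p
    A = np.triu(A, k=1)
    A = A | A.T
    return CoexpressionNetwork([f"g{i}" for i in range(n_nodes)], A)


def random_corr(n_genes, n_samples, seed):
    """Correlation matrix of random expression profiles."""
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n_genes, n_samples))
    corr = np.clip(np.corrcoef(data), -1, 1)
    return pd.DataFrame(
        corr, index=[f"g{i}" for i in range(n_genes)], columns=[f"g{i}" for i in range(n_genes)]
    )


@pytest.fixture(scope="session")
def full_design():
    """The reference 3-dose x 4-time x 2-replicate design (24 samples)."""
    return generate_design([0.0, 10.0, 100.0], [0.0, 3.0, 8.0, 24.0], 2)


@pytest.fixture(scope="session")
def small_dataset(full_design):
    """A small default-config simulated dataset shared across tests."""
    raw, det, truth = simulate_intensities(full_design, 1000, seed=11)
    return raw, det, truth


@pytest.fixture(scope="session")
def noise_only_dataset(full_design):
    """Two-component noise with no planted structure."""
    cfg = TruthConfig(plant_de=False, plant_modules=False)
    raw, det, truth = simulate_intensities(full_design, 1000, cfg, seed=7)
    return raw, det, truth
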