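import numpy as np
import pytest

from allograph import fixtures, parse_pdb
from allograph.graph_construction import build_graph


@pytest.fixture(scope="session")
def tripeptide_text():
    return fixtures.make_mini_pdb("tripeptide")


@pytest.fixture(scope="session")
def tripeptide(tripeptide_text):
    return parse_pdb(tripeptide_text)


@pytest.fixture(scope="session")
def tripeptide_graph(tripeptide):
    return build_graph(tripeptide)


@pytest.fixture(scope="session")
def helix10():
    return parse_pdb(fixtures.make_mini_pdb("helix10"))


@pytest.fixture(scope="session")
def dna4():
    return parse_pdb(fixtures.make_mini_pdb("dna4"))


@pytest.fixture(scope="session")
def dimer():
    return parse_pdb(fixtures.make_mini_pdb("dimer"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def dense_pseudoinverse(L):
    """Independent dense Moore-Penrose pseudoinverse via eigendecomposition."""
    L = np.asarray(L)
    vals, vecs = np.linalg.eigh(L)
    inv = np.where(np.abs(vals) > 1e-9 * np.abs(vals).max(), 1.0 / vals, 0.0)
    return (vecs * inv) @ vecs.T


def dense_transfer_operator(graph):
    """Brute-force dense M = 1/2 W B^T L^+ B for small graphs."""
    n, m = graph.n_atoms, graph.n_bonds
    B = np.zeros((n, m))
    B[graph.pair_u, np.arange(m)] = 1.0
    B[graph.pair_v, np.arange(m)] = -1.0
    W = np.diag(graph.pair_weight)
    L = B @ W @ B.T
    return 0.5 * W @ B.T @ dense_pseudoinverse(L) @ B
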