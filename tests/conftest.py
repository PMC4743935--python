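import numpy as np
import pytest

from chnmird import (
    SyntheticSpec,
    WalkConfig,
    build_knn_graph,
    build_transition,
    generate,
    integrate_layers,
)


@pytest.fixture(scope="session")
def default_data():
    """One default planted-module dataset, shared across the session."""
    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def networks(default_data):
    """(multigraph MFSN, phenotype KNN network, associations) triple."""
    mfsn = integrate_layers(list(default_data.layers))
    dpn = build_knn_graph(default_data.phenotype, k=5)
    return mfsn, dpn, default_data.associations


@pytest.fixture(scope="session")
def config():
    return WalkConfig()


@pytest.fixture
def toy_chn():
    """2 miRNAs {x, y}, 1 disease d: x linked to d, y only to x."""
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    B = np.zeros((1, 1))
    C = np.array([[1.0], [0.0]])
    return build_transition(A, B, C, lam=0.5)


def random_chn(rng: np.random.Generator, max_nodes: int = 30, connected: bool = True):
    """Random heterogeneous transition matrix for solver/stochasticity tests.

    With connected=True every miRNA has similarity edges and every
    disease has phenotype edges, so no zero rows occur.
    """
    m = int(rng.integers(3, max(4, (max_nodes * 2) // 3)))
    n = int(rng.integers(2, max(3, max_nodes - m)))
    W = rng.random((m, m))
    W = np.triu(W, 1)
    W = W + W.T
    Bw = rng.random((n, n))
    Bw = np.triu(Bw, 1)
    Bw = Bw + Bw.T
    if not connected:
        # knock out a few rows entirely to exercise degenerate handling
        for i in rng.choice(m, size=min(2, m - 1), replace=False):
            W[i, :] = W[:, i] = 0.0
        for j in rng.choice(n, size=1):
            Bw[j, :] = Bw[:, j] = 0.0
    C = (rng.random((m, n)) < 0.3).astype(float)
    from chnmird.multigraph import row_normalize

    return build_transition(row_normalize(W), Bw, C, lam=float(rng.uniform(0.1, 0.9)))
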