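"""Disease phenotype network: a weighted K-nearest-neighbour graph.

Phenotype similarity matrices are dense and noisy; keeping only each
disease's K most similar neighbours yields a sparse graph that preserves
the strongest phenotypic relationships.  Edges are taken as the union of
per-node neighbourhoods (i-j is an edge if j is among i's top K *or*
i among j's), which guarantees every node a degree of at least
min(K, n-1), and are weighted by the similarity score itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import NodeIndex, PhenotypeSimilarityMatrix

__all__ = ["PhenotypeNetwork", "build_knn_graph"]


@dataclass(frozen=True)
class PhenotypeNetwork:
    """Weighted disease-disease KNN adjacency (symmetric, zero diagonal)."""

    nodes: NodeIndex
    B: np.ndarray
    k: int

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.B.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if not np.allclose(self.B, self.B.T, atol=1e-12):
            raise ValueError("phenotype network adjacency must be symmetric")
        if np.any(self.B < 0):
            raise ValueError("phenotype network weights must be nonnegative")
        if np.any(np.diag(self.B) != 0):
            raise ValueError("phenotype network must have a zero diagonal")


def build_knn_graph(S: PhenotypeSimilarityMatrix, k: int = 5) -> PhenotypeNetwork:
    """Connect each disease to its k most phenotypically similar diseases.

    Neighbour selection ignores the diagonal.  Ties in similarity are
    broken by ascending disease identifier so the graph is reproducible.
    The default k=5 follows common practice for phenotype KNN networks.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    n = len(S.nodes)
    if n < 2:
        raise ValueError("need at least 2 diseases to build a KNN graph")
    ids = S.nodes.ids
    B = np.zeros((n, n))
    kk = min(k, n - 1)
    for i in range(n):
        # order candidates by similarity desc, then id asc (deterministic ties)
        order = sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (-S.scores[i, j], ids[j]),
        )
        for j in order[:kk]:
            B[i, j] = B[j, i] = S.scores[i, j]
    return PhenotypeNetwork(nodes=S.nodes, B=B, k=k)
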