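"""Build miRNA functional-similarity layers from target gene sets.

miRNAs act through the mRNAs they repress, so two miRNAs are considered
functionally similar when their target gene sets are functionally
similar.  A layer is produced by scoring every miRNA pair with a
pluggable gene-set similarity function; precomputed similarity layers
(e.g. from a PPI communication score or a GO semantic similarity tool)
can instead be loaded directly through :func:`chnmird.core_io.read_edge_list`.

The shipped gene-set similarities — Jaccard overlap and best-match
average over a gene-gene similarity matrix — are reference measures for
synthetic data and simple analyses; any callable with the same contract
(symmetric, nonnegative) plugs in.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .core_io import FormatError, NodeIndex, SimilarityLayer, normalize_id, _rows

logger = logging.getLogger("chnmird")

__all__ = [
    "TargetSets",
    "GeneSetSimilarityFn",
    "read_target_sets",
    "jaccard_setsim",
    "bma_setsim",
    "build_layer",
]

#: miRNA id -> set of target gene ids; every set has at least 2 targets.
TargetSets = Mapping[str, frozenset[str]]

#: (gene set, gene set) -> similarity score >= 0, symmetric in its arguments.
GeneSetSimilarityFn = Callable[[frozenset[str], frozenset[str]], float]


def read_target_sets(path: str | Path, min_targets: int = 2) -> dict[str, frozenset[str]]:
    """Read (miRNA, gene) TSV pairs into target sets.

    miRNAs with fewer than ``min_targets`` targets are dropped (a single
    shared target carries no set-similarity signal); the drop is logged.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    n_rows = 0
    for lineno, cols in _rows(path):
        n_rows += 1
        if len(cols) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns (mirna, gene)")
        sets.setdefault(normalize_id(cols[0]), set()).add(cols[1].strip())
    dropped = [m for m, s in sets.items() if len(s) < min_targets]
    for m in dropped:
        del sets[m]
    logger.info(
        "%s: %d rows read; %d miRNAs kept, %d dropped (< %d targets)",
        path, n_rows, len(sets), len(dropped), min_targets,
    )
    return {m: frozenset(s) for m, s in sets.items()}


def jaccard_setsim(S: frozenset[str] | set[str], T: frozenset[str] | set[str]) -> float:
    """Jaccard overlap |S ∩ T| / |S ∪ T| of two nonempty gene sets."""
    if not S or not T:
        raise ValueError("gene sets must be nonempty")
    S, T = set(S), set(T)
    return len(S & T) / len(S | T)


def bma_setsim(
    S: frozenset[str] | set[str],
    T: frozenset[str] | set[str],
    gene_sim: np.ndarray,
    gene_index: NodeIndex,
) -> float:
    """Best-match-average similarity of two gene sets.

    Each gene in S is matched to its most similar gene in T and vice
    versa; the two directional means are averaged, which makes the score
    symmetric.  ``gene_sim`` is any symmetric nonnegative gene-gene
    similarity matrix indexed by ``gene_index``.
    """
    if not S or not T:
        raise ValueError("gene sets must be nonempty")
    for g in set(S) | set(T):
        if g not in gene_index:
            raise KeyError(f"gene {g!r} missing from the gene similarity matrix")
    si = [gene_index.position(g) for g in sorted(S)]
    ti = [gene_index.position(g) for g in sorted(T)]
    block = gene_sim[np.ix_(si, ti)]
    return float(block.max(axis=1).mean() + block.max(axis=0).mean()) / 2.0


def build_layer(
    targets: TargetSets, sim: GeneSetSimilarityFn, name: str
) -> SimilarityLayer:
    """Score every miRNA pair by target-set similarity.

    The output weight matrix is symmetric with a zero diagonal
    (self-similarity is not an edge).  A similarity function returning a
    negative or non-finite score aborts with the offending pair named.
    """
    if len(targets) < 2:
        raise ValueError("need at least 2 miRNAs to build a similarity layer")
    nodes = NodeIndex(sorted(targets))
    m = len(nodes)
    W = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a, b = nodes.lookup(i), nodes.lookup(j)
            s = float(sim(targets[a], targets[b]))
            if not np.isfinite(s) or s < 0:
                raise ValueError(
                    f"similarity function returned {s} for pair ({a!r}, {b!r})"
                )
            W[i, j] = W[j, i] = s
    return SimilarityLayer(name=name, nodes=nodes, weights=W)
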