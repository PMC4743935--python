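"""Integrate several similarity layers into one multigraph transition matrix.

Each layer k contributes its own row-normalised transition matrix A^k,
defined over that layer's node set.  On the merged multigraph the walker
first picks, uniformly, one of the N_i layers that contain node i and
then steps according to that layer's transition row:

    A(i, j) = sum_k (1 / N_i) * A^k(i, j)      over layers k containing i.

N_i is the number of layers node i is a member of, where membership means
appearing in the layer's edge list (its node set).  A node isolated in
every layer keeps an all-zero row; restart mass keeps the walk well
defined there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import NodeIndex, SimilarityLayer

logger = logging.getLogger("chnmird")

__all__ = ["MultigraphMFSN", "row_normalize", "integrate_layers"]


def row_normalize(W: np.ndarray) -> np.ndarray:
    """Divide each nonzero row by its sum; all-zero rows stay zero.

    The result is row-stochastic up to zero rows, which downstream code
    treats as absorbing-but-restartable states.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("row_normalize: negative entries are not allowed")
    sums = W.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(sums > 0, W / sums, 0.0)
    return A


@dataclass(frozen=True)
class MultigraphMFSN:
    """Integrated multigraph miRNA functional-similarity network.

    ``A`` is the expected transition matrix over the union node set;
    ``membership`` records which layers each miRNA belongs to.
    """

    nodes: NodeIndex
    A: np.ndarray
    membership: dict[str, frozenset[str]]
    n_layers: int

    def __post_init__(self) -> None:
        m = len(self.nodes)
        if self.A.shape != (m, m):
            raise ValueError("transition matrix shape does not match node count")
        if np.any(self.A < 0):
            raise ValueError("transition matrix must be nonnegative")
        sums = self.A.sum(axis=1)
        # rows sum to 1 when the node has edges in every layer it belongs
        # to; a membership with no edges dilutes the row below 1
        if np.any(sums > 1 + 1e-9):
            bad = self.nodes.lookup(int(np.argmax(sums)))
            raise ValueError(f"row for {bad!r} sums above 1")


def integrate_layers(layers: Sequence[SimilarityLayer]) -> MultigraphMFSN:
    """Average per-layer transition rows with equal layer-choice weight.

    Layers may cover different miRNA sets; a node's row averages only the
    layers it belongs to (weight 1/N_i each).  A node that is a member of
    a layer but isolated in it contributes a zero row for that layer,
    diluting the average — this is logged because it means part of the
    walker's step probability is lost at that node.
    """
    if not layers:
        raise ValueError("need at least one layer to integrate")
    union = sorted(set().union(*(set(l.nodes.ids) for l in layers)))
    nodes = NodeIndex(union)
    m = len(nodes)
    A = np.zeros((m, m))
    n_i = np.zeros(m)
    membership: dict[str, set[str]] = {v: set() for v in union}

    for layer in layers:
        Ak = row_normalize(layer.weights)
        idx = np.array([nodes.position(v) for v in layer.nodes.ids])
        A[np.ix_(idx, idx)] += Ak
        n_i[idx] += 1
        zero_rows = np.where(Ak.sum(axis=1) == 0)[0]
        for r in zero_rows:
            logger.info(
                "node %r is a member of layer %r but isolated in it",
                layer.nodes.lookup(int(r)), layer.name,
            )
        for v in layer.nodes.ids:
            membership[v].add(layer.name)

    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(n_i[:, None] > 0, A / np.maximum(n_i, 1)[:, None], 0.0)
    return MultigraphMFSN(
        nodes=nodes,
        A=A,
        membership={v: frozenset(s) for v, s in membership.items()},
        n_layers=len(layers),
    )
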