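"""Domain types and plain-text readers/writers.

The package works with three kinds of on-disk objects, all tab-separated
UTF-8 text:

* weighted miRNA-miRNA functional-similarity **edge lists**
  (``node_a<TAB>node_b<TAB>weight``),
* binary miRNA-disease **association pair lists**
  (``mirna<TAB>disease``),
* square disease-disease **phenotype similarity matrices** with a header
  row and an index column of disease identifiers.

Everything downstream (multigraph integration, KNN phenotype graph,
heterogeneous-network assembly) consumes the in-memory types defined here.
Node orderings that are implicit in the matrix algebra are made explicit
through :class:`NodeIndex`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("chnmird")

__all__ = [
    "FormatError",
    "NodeIndex",
    "SimilarityLayer",
    "PhenotypeSimilarityMatrix",
    "AssociationSet",
    "normalize_id",
    "read_edge_list",
    "read_similarity_matrix",
    "write_edge_list",
    "write_similarity_matrix",
    "write_ranking",
    "read_ranking",
    "load_config",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


# matches the common mature-miRNA prefix in any capitalisation
_MIR_PREFIX = re.compile(r"^(hsa)-(mir|let)-(.+)$", re.IGNORECASE)


def normalize_id(raw: str) -> str:
    """Canonicalise a node identifier.

    Surrounding whitespace is stripped and the species/family prefix of
    mature miRNA names is case-folded to the miRBase convention
    (``hsa-miR-…`` / ``hsa-let-…``).  Database exports disagree on the
    capitalisation of these prefixes; anything else (disease IDs, gene
    symbols) passes through untouched so that genuinely distinct
    identifiers are never merged.  Every rewrite is logged so the mapping
    is auditable.
    """
    ident = raw.strip()
    m = _MIR_PREFIX.match(ident)
    if m:
        family = "let" if m.group(2).lower() == "let" else "miR"
        canonical = f"{m.group(1).lower()}-{family}-{m.group(3)}"
        if canonical != ident:
            logger.info("identifier normalised: %r -> %r", ident, canonical)
        ident = canonical
    elif ident != raw:
        logger.debug("identifier stripped: %r -> %r", raw, ident)
    return ident


class NodeIndex:
    """Immutable bijection between node identifiers and matrix offsets.

    Positions are contiguous from 0 in the order the identifiers are
    given; ``lookup(position(i)) == i`` for every id.
    """

    __slots__ = ("_ids", "_pos")

    def __init__(self, ids: Iterable[str]):
        self._ids: tuple[str, ...] = tuple(ids)
        self._pos: dict[str, int] = {v: i for i, v in enumerate(self._ids)}
        if len(self._pos) != len(self._ids):
            seen: set[str] = set()
            dup = next(i for i in self._ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate identifier in NodeIndex: {dup!r}")

    @property
    def ids(self) -> tuple[str, ...]:
        return self._ids

    def position(self, ident: str) -> int:
        return self._pos[ident]

    def lookup(self, offset: int) -> str:
        return self._ids[offset]

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, ident: object) -> bool:
        return ident in self._pos

    def __iter__(self):
        return iter(self._ids)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NodeIndex) and self._ids == other._ids

    def __hash__(self) -> int:
        return hash(self._ids)

    def __repr__(self) -> str:
        return f"NodeIndex({len(self)} ids)"


def _check_symmetric_nonneg(W: np.ndarray, what: str, zero_diag: bool = True) -> None:
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"{what}: matrix must be square, got {W.shape}")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError(f"{what}: matrix must be symmetric")
    if np.any(W < 0):
        raise ValueError(f"{what}: negative entries are not allowed")
    if zero_diag and np.any(np.diag(W) != 0):
        raise ValueError(f"{what}: diagonal must be zero (no self-similarity edges)")


@dataclass(frozen=True)
class SimilarityLayer:
    """One weighted miRNA functional-similarity network.

    A layer corresponds to a single data source (e.g. protein-protein
    interactions or one GO sub-ontology) scoring the functional
    relatedness of miRNA pairs through their target gene sets.  Weights
    are symmetric, nonnegative and carry a zero diagonal.
    """

    name: str
    nodes: NodeIndex
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.weights.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weights shape does not match node count")
        _check_symmetric_nonneg(self.weights, f"layer {self.name!r}")


@dataclass(frozen=True)
class PhenotypeSimilarityMatrix:
    """Pairwise disease-phenotype similarity scores in [0, 1].

    Produced upstream by text mining of clinical phenotype descriptions
    (MimMiner-style); this package consumes the scores, it does not
    compute them.
    """

    nodes: NodeIndex
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = self.scores
        if s.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("scores shape does not match node count")
        if not np.allclose(s, s.T, atol=1e-12):
            raise ValueError("phenotype similarity matrix must be symmetric")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("phenotype similarities must lie in [0, 1]")

    def similarity(self, a: str, b: str) -> float:
        return float(self.scores[self.nodes.position(a), self.nodes.position(b)])


@dataclass(frozen=True)
class AssociationSet:
    """Known miRNA-disease associations (the bipartite bridge relation).

    Stored as a duplicate-free set of ``(mirna, disease)`` pairs; the 0/1
    incidence matrix C is materialised on demand against explicit node
    indexes so it always aligns with whatever miRNA / disease ordering the
    surrounding networks use.
    """

    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationSet":
        seen: set[tuple[str, str]] = set()
        dups = 0
        for p in pairs:
            if p in seen:
                dups += 1
            seen.add(p)
        if dups:
            logger.warning("collapsed %d duplicate association pairs", dups)
        return cls(frozenset(seen))

    @property
    def mirnas(self) -> tuple[str, ...]:
        return tuple(sorted({m for m, _ in self.pairs}))

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted({d for _, d in self.pairs}))

    def mirnas_of(self, disease: str) -> frozenset[str]:
        return frozenset(m for m, d in self.pairs if d == disease)

    def without(self, removed: Iterable[tuple[str, str]]) -> "AssociationSet":
        return AssociationSet(self.pairs - frozenset(removed))

    def incidence(self, mirna_index: NodeIndex, disease_index: NodeIndex) -> np.ndarray:
        """Build the m x n 0/1 matrix C against the given orderings.

        Pairs whose miRNA or disease is absent from the indexes are
        dropped with a log message; a data source that does not cover a
        miRNA simply cannot link it.
        """
        C = np.zeros((len(mirna_index), len(disease_index)))
        missing = 0
        for m, d in self.pairs:
            if m in mirna_index and d in disease_index:
                C[mirna_index.position(m), disease_index.position(d)] = 1.0
            else:
                missing += 1
        if missing:
            logger.info(
                "%d association pairs fall outside the network node sets", missing
            )
        return C

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _rows(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            yield lineno, line.split("\t")


def read_edge_list(
    path: str | Path, kind: str = "layer", name: str | None = None
) -> SimilarityLayer | AssociationSet:
    """Read a TSV edge list as a similarity layer or an association set.

    ``kind="layer"`` expects three columns (node_a, node_b, weight) and
    materialises the symmetric weight matrix; ``kind="associations"``
    expects two columns (mirna, disease) and collapses duplicates.
    Malformed rows, negative weights, self-loops and conflicting duplicate
    edge weights are rejected with the offending line number; no row is
    ever silently dropped.
    """
    path = Path(path)
    if kind not in ("layer", "associations"):
        raise ValueError(f"unknown edge-list kind: {kind!r}")

    if kind == "associations":
        pairs: list[tuple[str, str]] = []
        n_rows = 0
        for lineno, cols in _rows(path):
            n_rows += 1
            if len(cols) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns (mirna, disease), got {len(cols)}"
                )
            pairs.append((normalize_id(cols[0]), normalize_id(cols[1])))
        logger.info("%s: %d rows read, 0 rejected", path, n_rows)
        return AssociationSet.from_pairs(pairs)

    edges: dict[tuple[str, str], float] = {}
    order: list[str] = []
    seen: set[str] = set()
    n_rows = 0
    for lineno, cols in _rows(path):
        n_rows += 1
        if len(cols) != 3:
            raise FormatError(
                f"{path}:{lineno}: expected 3 columns (node_a, node_b, weight), got {len(cols)}"
            )
        a, b = normalize_id(cols[0]), normalize_id(cols[1])
        try:
            w = float(cols[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: weight {cols[2]!r} is not a number")
        if not np.isfinite(w) or w < 0:
            raise FormatError(f"{path}:{lineno}: negative or non-finite weight {w}")
        if a == b:
            raise FormatError(f"{path}:{lineno}: self-loop on {a!r} is not allowed")
        key = (a, b) if a <= b else (b, a)
        if key in edges and edges[key] != w:
            raise FormatError(
                f"{path}:{lineno}: conflicting duplicate edge {a}-{b} "
                f"({edges[key]} vs {w})"
            )
        edges[key] = w
        for node in (a, b):
            if node not in seen:
                seen.add(node)
                order.append(node)
    logger.info("%s: %d rows read, 0 rejected", path, n_rows)
    nodes = NodeIndex(order)
    W = np.zeros((len(nodes), len(nodes)))
    for (a, b), w in edges.items():
        i, j = nodes.position(a), nodes.position(b)
        W[i, j] = W[j, i] = w
    return SimilarityLayer(name=name or path.stem, nodes=nodes, weights=W)


def read_similarity_matrix(path: str | Path) -> PhenotypeSimilarityMatrix:
    """Read a square TSV similarity matrix with an ID header row/column.

    Small asymmetries are repaired by averaging (S + S^T)/2; anything
    larger than 1e-9 triggers a warning so upstream data problems are
    visible.  Entries must lie in [0, 1].
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids_row = [normalize_id(str(c)) for c in df.columns]
    ids_col = [normalize_id(str(i)) for i in df.index]
    if ids_row != ids_col:
        raise FormatError(f"{path}: matrix is not square over a single ID set")
    S = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(S)):
        raise FormatError(f"{path}: non-finite entries")
    if np.any(S < 0) or np.any(S > 1):
        bad = np.argwhere((S < 0) | (S > 1))[0]
        raise FormatError(
            f"{path}: entry ({ids_col[bad[0]]}, {ids_row[bad[1]]}) = "
            f"{S[bad[0], bad[1]]} outside [0, 1]"
        )
    asym = float(np.abs(S - S.T).max())
    if asym > 1e-9:
        logger.warning("%s: max asymmetry %.3g, symmetrising by averaging", path, asym)
    S = (S + S.T) / 2.0
    return PhenotypeSimilarityMatrix(nodes=NodeIndex(ids_col), scores=S)


def write_edge_list(path: str | Path, obj: SimilarityLayer | AssociationSet) -> None:
    """Write a layer (each undirected edge once, a <= b) or association set."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if isinstance(obj, AssociationSet):
            for m, d in sorted(obj.pairs):
                fh.write(f"{m}\t{d}\n")
            return
        ids = obj.nodes.ids
        W = obj.weights
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if W[i, j] != 0:
                    a, b = sorted((ids[i], ids[j]))
                    fh.write(f"{a}\t{b}\t{float(W[i, j])!r}\n")


def write_similarity_matrix(path: str | Path, sim: PhenotypeSimilarityMatrix) -> None:
    df = pd.DataFrame(sim.scores, index=list(sim.nodes.ids), columns=list(sim.nodes.ids))
    df.to_csv(path, sep="\t")


def write_ranking(path: str | Path, ranking: Sequence[tuple[str, float]]) -> None:
    """Write a candidate ranking as TSV (rank, miRNA, score).

    Rows are sorted by descending score with ties broken by ascending
    miRNA identifier; ranks start at 1.
    """
    if not ranking:
        raise ValueError("refusing to write an empty ranking")
    ordered = sorted(ranking, key=lambda t: (-t[1], t[0]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tmiRNA\tscore\n")
        for r, (m, s) in enumerate(ordered, start=1):
            fh.write(f"{r}\t{m}\t{float(s)!r}\n")


def read_ranking(path: str | Path) -> list[tuple[str, float]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(m), float(s)) for m, s in zip(df["miRNA"], df["score"])]


_CONFIG_DEFAULTS: dict[str, float | int] = {
    "alpha": 0.7,
    "lambda": 0.5,
    "eta": 0.5,
    "knn_k": 5,
    "tol": 1e-10,
    "max_iter": 10_000,
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML run configuration, filling in the standard defaults."""
    import yaml

    cfg: dict = dict(_CONFIG_DEFAULTS)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise FormatError(f"{path}: config must be a mapping")
        cfg.update(user)
    return cfg
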