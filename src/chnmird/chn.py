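"""Assemble the complex heterogeneous network (CHN).

The CHN couples the integrated multigraph miRNA network (transition
matrix A, m x m) to the disease phenotype network (adjacency B, n x n)
through the bipartite known-association incidence C (m x n, 0/1).  Its
block adjacency is [A C; C^T B], and the walker's transition matrix M
splits each node's step probability between staying inside its own
network and jumping across an association edge with probability λ:

    M_miRmiR(i,·) = A(i,·)                 if miRNA i has no disease links
                  = (1-λ) · A(i,·)         otherwise
    M_DD(i,·)     = rownorm(B)(i,·)        if disease i has no miRNA links
                  = (1-λ) · rownorm(B)(i,·) otherwise
    M_miRD(i,j)   = λ · C(i,j) / Σ_j C(i,j)   (0 if the row sum is 0)
    M_DmiR(i,j)   = λ · C(j,i) / Σ_j C(j,i)   (0 if the column sum is 0)

A node whose within-block row is zero but which does have association
links would otherwise emit only mass λ per step; its cross-block entries
are rescaled to sum to 1 so the walk stays probability-conserving (the
rescue is logged).  A node isolated in both blocks keeps an all-zero
row — the restart term prevents the walker from being trapped there.

The initial probability vector places mass (1-η) uniformly on the seed
miRNAs and mass η uniformly on the seed diseases:

    P₀ = [(1-η)·u₀ ; η·v₀].

When no seed miRNA exists (e.g. a disease with no known miRNAs) all the
mass goes to the disease block, P₀ = [0 ; v₀]; rankings are invariant to
positive rescaling of P₀, so renormalising to total mass 1 changes no
ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import AssociationSet, NodeIndex
from .dpn import PhenotypeNetwork
from .multigraph import MultigraphMFSN, row_normalize

logger = logging.getLogger("chnmird")

__all__ = ["WalkConfig", "SeedSet", "CHNModel", "build_transition", "assemble_chn",
           "build_initial_vector"]


@dataclass(frozen=True)
class WalkConfig:
    """Walk parameters.

    alpha — restart probability in (0, 1]; 0.7 balances local and global
    network structure and prioritisation results are known to be robust
    to it.  lam — probability of jumping between the miRNA and disease
    networks along association edges.  eta — share of the initial
    probability mass placed on the seed diseases (the rest goes to seed
    miRNAs).  Iteration stops when the L1 change between successive
    probability vectors falls below tol.
    """

    alpha: float = 0.7
    lam: float = 0.5
    eta: float = 0.5
    tol: float = 1e-10
    max_iter: int = 10_000
    knn_k: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 < self.lam < 1:
            raise ValueError("lambda must lie in (0, 1)")
        if not 0 < self.eta < 1:
            raise ValueError("eta must lie in (0, 1)")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be positive and max_iter >= 1")


@dataclass(frozen=True)
class SeedSet:
    """Seed nodes for one query: known disease miRNAs plus the disease itself.

    seed_mirnas may be empty (a disease without any known miRNA);
    seed_diseases may not.
    """

    seed_mirnas: frozenset[str]
    seed_diseases: frozenset[str]

    def __post_init__(self) -> None:
        if not self.seed_diseases:
            raise ValueError("seed_diseases must be nonempty")


@dataclass(frozen=True)
class CHNModel:
    """The assembled heterogeneous transition structure."""

    M: np.ndarray
    lam: float
    mirna_index: NodeIndex
    disease_index: NodeIndex

    @property
    def m(self) -> int:
        return len(self.mirna_index)

    @property
    def n(self) -> int:
        return len(self.disease_index)


def build_transition(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    lam: float,
    mirna_index: NodeIndex | None = None,
    disease_index: NodeIndex | None = None,
) -> CHNModel:
    """Build the (m+n) x (m+n) CHN transition matrix M.

    A must already be row-stochastic-or-zero; B is any nonnegative
    adjacency (row-normalised here); C is the 0/1 incidence.  Every row
    of M sums to 1 except rows of nodes isolated in both blocks, which
    stay zero.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    m, n = C.shape
    if A.shape != (m, m) or B.shape != (n, n):
        raise ValueError(
            f"dimension mismatch: A {A.shape}, B {B.shape}, C {C.shape}"
        )
    if not 0 < lam < 1:
        raise ValueError("lambda must lie in (0, 1)")
    if np.any((C != 0) & (C != 1)):
        raise ValueError("C must be a 0/1 incidence matrix")

    Bn = row_normalize(B)
    a_deg = A.sum(axis=1)   # 1 or 0 per row
    b_deg = Bn.sum(axis=1)
    c_row = C.sum(axis=1)   # miRNA-side association degree
    c_col = C.sum(axis=0)   # disease-side association degree

    M = np.zeros((m + n, m + n))

    # miRNA rows
    mm_scale = np.where(c_row > 0, 1.0 - lam, 1.0)
    M[:m, :m] = A * mm_scale[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        Cn = np.where(c_row[:, None] > 0, C / np.maximum(c_row, 1)[:, None], 0.0)
    md_scale = np.full(m, lam)
    rescued = (a_deg == 0) & (c_row > 0)
    if np.any(rescued):
        md_scale = np.where(rescued, 1.0, md_scale)
        for i in np.where(rescued)[0]:
            name = mirna_index.lookup(int(i)) if mirna_index else f"miRNA[{i}]"
            logger.info(
                "%s has association links but no similarity edges; "
                "cross-block row rescaled to sum 1", name,
            )
    M[:m, m:] = Cn * md_scale[:, None]

    # disease rows
    dd_scale = np.where(c_col > 0, 1.0 - lam, 1.0)
    M[m:, m:] = Bn * dd_scale[:, None]
    Ct = C.T
    with np.errstate(invalid="ignore", divide="ignore"):
        Ctn = np.where(c_col[:, None] > 0, Ct / np.maximum(c_col, 1)[:, None], 0.0)
    dm_scale = np.full(n, lam)
    rescued_d = (b_deg == 0) & (c_col > 0)
    if np.any(rescued_d):
        dm_scale = np.where(rescued_d, 1.0, dm_scale)
        for j in np.where(rescued_d)[0]:
            name = disease_index.lookup(int(j)) if disease_index else f"disease[{j}]"
            logger.info(
                "%s has association links but no phenotype edges; "
                "cross-block row rescaled to sum 1", name,
            )
    M[m:, :m] = Ctn * dm_scale[:, None]

    dead = np.where(M.sum(axis=1) == 0)[0]
    for i in dead:
        logger.info("node %d is isolated in both blocks; row kept zero", int(i))

    return CHNModel(
        M=M,
        lam=lam,
        mirna_index=mirna_index or NodeIndex(f"miR_{i}" for i in range(m)),
        disease_index=disease_index or NodeIndex(f"d_{j}" for j in range(n)),
    )


def assemble_chn(
    mfsn: MultigraphMFSN,
    dpn: PhenotypeNetwork,
    associations: AssociationSet,
    lam: float,
) -> CHNModel:
    """Convenience assembly from the three network objects."""
    C = associations.incidence(mfsn.nodes, dpn.nodes)
    return build_transition(
        mfsn.A, dpn.B, C, lam, mirna_index=mfsn.nodes, disease_index=dpn.nodes
    )


def build_initial_vector(
    seeds: SeedSet,
    eta: float,
    mirna_index: NodeIndex,
    disease_index: NodeIndex,
) -> np.ndarray:
    """Initial probability vector P₀ over the concatenated node set.

    Uniform over seed miRNAs with total mass (1-η) and uniform over seed
    diseases with total mass η; with no seed miRNAs the disease block
    receives full mass 1.
    """
    if not 0 < eta < 1:
        raise ValueError("eta must lie in (0, 1)")
    for s in seeds.seed_mirnas:
        if s not in mirna_index:
            raise KeyError(f"seed miRNA {s!r} not in the miRNA index")
    for s in seeds.seed_diseases:
        if s not in disease_index:
            raise KeyError(f"seed disease {s!r} not in the disease index")
    m, n = len(mirna_index), len(disease_index)
    P0 = np.zeros(m + n)
    if seeds.seed_mirnas:
        u_mass, v_mass = 1.0 - eta, eta
        for s in seeds.seed_mirnas:
            P0[mirna_index.position(s)] = u_mass / len(seeds.seed_mirnas)
    else:
        v_mass = 1.0
    for s in seeds.seed_diseases:
        P0[m + disease_index.position(s)] = v_mass / len(seeds.seed_diseases)
    return P0
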