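"""Evaluation protocol: cross-validation, nulls, robustness, baselines.

The central experiment is per-disease 5-fold cross-validation with a
rank-threshold ROC.  For each disease with at least ``min_mirnas`` known
miRNAs, its known miRNAs are split into folds; per fold, the held-out
associations are removed from the incidence matrix C *before* the
heterogeneous network is assembled (otherwise the walk literally sees
the answer — this is asserted, not assumed), the remaining known miRNAs
plus the disease seed the walk, and each held-out miRNA's rank among the
candidate set (all miRNAs without a known association to the disease) is
recorded.

ROC construction: each test case is summarised by its normalised rank
position x = (rank - 1) / (n_candidates - 1), the fraction of candidates
ranked above it.  Sweeping a rank-fraction cutoff t gives sensitivity
TPR(t) = fraction of test cases with x <= t, while a cutoff admitting
the top fraction t of a candidate list admits that same fraction of its
non-associated candidates, so FPR(t) = t.  The area under this curve
equals the mean of (n_candidates - rank)/(n_candidates - 1) over test
cases; :func:`rank_auc` integrates the swept curve and the closed form
is exposed separately as an independent cross-check.

Also provided: a randomization null (seed sets replaced by random
decoys of equal size), leave-one-disease-out top-N counting (every
association of the query disease deleted; the disease alone seeds the
walk), a (λ, η) parameter sweep on a shared fold partition, random
association dropout for robustness, and a single-network
random-walk-with-restart baseline on the miRNA multigraph alone
(RWRMDA-style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chn import SeedSet, WalkConfig, assemble_chn
from .core_io import AssociationSet
from .dpn import PhenotypeNetwork
from .multigraph import MultigraphMFSN
from .ranking import rank_candidates
from .rwr import rwr_iterate

logger = logging.getLogger("chnmird")

__all__ = [
    "CaseRank",
    "CVResult",
    "rank_auc",
    "mean_percentile_auc",
    "roc_points",
    "cross_validate",
    "randomization_test",
    "loo_disease_topn",
    "parameter_sweep",
    "rwrmda_baseline",
    "sample_dropout",
    "association_dropout",
]


@dataclass(frozen=True)
class CaseRank:
    """One held-out test case: where its miRNA landed among the candidates."""

    disease: str
    mirna: str
    rank: int
    n_candidates: int
    fold: int


@dataclass(frozen=True)
class CVResult:
    cases: tuple[CaseRank, ...]
    pooled_auc: float
    per_disease_auc: dict[str, float]
    rng_seed: int


# ---------------------------------------------------------------------------
# rank-threshold ROC
# ---------------------------------------------------------------------------


def _normalized_positions(ranks: list[tuple[int, int]]) -> np.ndarray:
    if not ranks:
        raise ValueError("need at least one test case")
    xs = []
    for rank, n_cand in ranks:
        if not 1 <= rank <= n_cand:
            raise ValueError(f"rank {rank} outside 1..{n_cand}")
        if n_cand < 2:
            raise ValueError("a test case needs at least 2 candidates")
        xs.append((rank - 1) / (n_cand - 1))
    return np.asarray(xs)


def roc_points(ranks: list[tuple[int, int]]) -> np.ndarray:
    """(FPR, TPR) polyline from sweeping the rank-fraction cutoff."""
    x = _normalized_positions(ranks)
    n = len(x)
    values = np.unique(x)
    pts = [(0.0, 0.0)]
    for v in values:
        below = float(np.sum(x < v)) / n
        upto = float(np.sum(x <= v)) / n
        pts.append((float(v), below))
        pts.append((float(v), upto))
    pts.append((1.0, 1.0))
    return np.asarray(pts)


def rank_auc(ranks: list[tuple[int, int]]) -> float:
    """AUC of the rank-threshold ROC (trapezoid over the swept curve)."""
    pts = roc_points(ranks)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def mean_percentile_auc(ranks: list[tuple[int, int]]) -> float:
    """Closed form: mean over cases of (n_candidates - rank)/(n_candidates - 1).

    Independent of the threshold sweep; used to cross-check it.
    """
    x = _normalized_positions(ranks)
    return float(np.mean(1.0 - x))


# ---------------------------------------------------------------------------
# cross-validation engine
# ---------------------------------------------------------------------------


def _eligible_diseases(
    mfsn: MultigraphMFSN,
    dpn: PhenotypeNetwork,
    assoc: AssociationSet,
    min_mirnas: int,
) -> dict[str, list[str]]:
    """Diseases in the phenotype network with >= min_mirnas known miRNAs
    that the miRNA network covers."""
    covered = set(mfsn.nodes.ids)
    out: dict[str, list[str]] = {}
    for d in sorted(assoc.diseases):
        if d not in dpn.nodes:
            continue
        known = sorted(m for m in assoc.mirnas_of(d) if m in covered)
        if len(known) >= min_mirnas:
            out[d] = known
    return out


def _fold_split(items: list[str], folds: int, rng: np.random.Generator) -> list[list[str]]:
    """Shuffle then deal round-robin, so fold sizes differ by at most 1."""
    perm = rng.permutation(len(items))
    return [[items[perm[i]] for i in range(f, len(items), folds)] for f in range(folds)]


def _score_fold(
    mfsn: MultigraphMFSN,
    dpn: PhenotypeNetwork,
    assoc_fold: AssociationSet,
    config: WalkConfig,
    disease: str,
    seed_mirnas: list[str],
    test: list[str],
    fold: int,
) -> list[CaseRank]:
    model = assemble_chn(mfsn, dpn, assoc_fold, config.lam)
    seeds = SeedSet(frozenset(seed_mirnas), frozenset({disease}))
    ranking = rank_candidates(model, config, seeds)
    pos = {mirna: r for r, (mirna, _) in enumerate(ranking, start=1)}
    return [
        CaseRank(disease, t, pos[t], len(ranking), fold) for t in sorted(test)
    ]


def _pool(cases: list[CaseRank], rng_seed: int) -> CVResult:
    pooled = rank_auc([(c.rank, c.n_candidates) for c in cases])
    per_disease = {}
    for d in sorted({c.disease for c in cases}):
        dc = [(c.rank, c.n_candidates) for c in cases if c.disease == d]
        per_disease[d] = rank_auc(dc)
    return CVResult(tuple(cases), pooled, per_disease, rng_seed)


def cross_validate(
    mfsn: MultigraphMFSN,
    dpn: PhenotypeNetwork,
    associations: AssociationSet,
    config: WalkConfig,
    folds: int = 5,
    min_mirnas: int = 5,
    rng_seed: int = 0,
    leak_held_out: bool = False,
) -> CVResult:
    """Per-disease k-fold cross-validation with pooled rank-threshold AUC.

    ``leak_held_out=True`` deliberately leaves the held-out pairs inside C
    while the network is assembled.  It exists purely as a diagnostic for
    the leakage regression test; the resulting AUC is meaningless as a
    performance estimate.
    """
    rng = np.random.default_rng(rng_seed)
    eligible = _eligible_diseases(mfsn, dpn, associations, min_mirnas)
    if not eligible:
        raise ValueError(f"no disease has >= {min_mirnas} known miRNAs")
    cases: list[CaseRank] = []
    for disease, known in eligible.items():
        if len(known) < folds:
            raise ValueError(
                f"{disease} has {len(known)} known miRNAs, fewer than {folds} folds"
            )
        for f, test in enumerate(_fold_split(known, folds, rng)):
            train = [m for m in known if m not in set(test)]
            held_pairs = {(t, disease) for t in test}
            assoc_fold = associations if leak_held_out else associations.without(held_pairs)
            if not leak_held_out:
                # no-leakage invariant: the walk must never see a test pair
                assert not (held_pairs & assoc_fold.pairs)
            cases.extend(
                _score_fold(mfsn, dpn, assoc_fold, config, disease, train, test, f)
            )
    return _pool(cases, rng_seed)


def randomization_test(
    mfsn: MultigraphMFSN,
    dpn: PhenotypeNetwork,
    associations: AssociationSet,
    config: WalkConfig,
    n_reps: int,
    rng_seed: int = 0,
    folds: int = 5,
    min_mirnas: int = 5,
) -> list[float]:
    """Null AUC distribution: seed miRNA sets replaced by random decoys.

    Per repetition, every disease's known miRNA set in C is replaced by
    an equal-size set drawn uniformly at random from all miRNAs, so the
    association structure carries no relation to the truth; the
    cross-validation protocol then runs unchanged, still testing the
    *real* held-out miRNAs.  For the query disease, the decoys seeding a
    fold are drawn excluding only that fold's test miRNAs (a test miRNA
    that became a seed could not be ranked); this keeps test miRNAs
    exchangeable with the rest of the candidate pool, so the pooled AUC
    concentrates near 0.5.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    all_mirnas = list(mfsn.nodes.ids)
    aucs: list[float] = []
    for _ in range(n_reps):
        eligible = _eligible_diseases(mfsn, dpn, associations, min_mirnas)
        # uniform decoy columns for every disease, keeping C's degree profile
        base_pairs: set[tuple[str, str]] = set()
        for d in sorted(associations.diseases):
            size = min(len(associations.mirnas_of(d)), len(all_mirnas))
            picked = rng.choice(len(all_mirnas), size=size, replace=False)
            base_pairs.update((all_mirnas[i], d) for i in picked)
        cases: list[CaseRank] = []
        for disease, known in eligible.items():
            other_pairs = {(m, e) for m, e in base_pairs if e != disease}
            for f, test in enumerate(_fold_split(known, folds, rng)):
                pool = [m for m in all_mirnas if m not in set(test)]
                n_seeds = len(known) - len(test)
                idx = rng.choice(len(pool), size=n_seeds, replace=False)
                seed_mirnas = sorted(pool[i] for i in idx)
                assoc_fold = AssociationSet(
                    frozenset(other_pairs | {(m, disease) for m in seed_mirnas})
                )
                cases.extend(
                    _score_fold(
                        mfsn, dpn, assoc_fold, config,
                        disease, seed_mirnas, test, f,
                    )
                )
        aucs.append(_pool(cases, rng_seed).pooled_auc)
    return aucs


def loo_disease_topn(
    mfsn: MultigraphMFSN,
    dpn: PhenotypeNetwork,
    associations: AssociationSet,
    config: WalkConfig,
    n_list: tuple[int, ...] = (1, 5, 10, 20, 50),
) -> dict[int, int]:
    """Leave-one-disease-out recovery counts.

    Each disease in turn loses *all* its associations; seeded by the
    disease alone, the walk ranks every miRNA, and known disease miRNAs
    landing in the top N are counted, summed over diseases.  This probes
    the regime where a disease has no known miRNAs at all.
    """
    covered = set(mfsn.nodes.ids)
    counts = {N: 0 for N in n_list}
    for disease in sorted(associations.diseases):
        if disease not in dpn.nodes:
            continue
        known = sorted(m for m in associations.mirnas_of(disease) if m in covered)
        if not known:
            continue
        stripped = associations.without(
            {(m, disease) for m in associations.mirnas_of(disease)}
        )
        model = assemble_chn(mfsn, dpn, stripped, config.lam)
        seeds = SeedSet(frozenset(), frozenset({disease}))
        ranking = rank_candidates(model, config, seeds)
        pos = {mirna: r for r, (mirna, _) in enumerate(ranking, start=1)}
        for N in n_list:
            counts[N] += sum(1 for m in known if pos[m] <= N)
    return counts


def parameter_sweep(
    mfsn: MultigraphMFSN,
    dpn: PhenotypeNetwork,
    associations: AssociationSet,
    lambdas: list[float],
    etas: list[float],
    config: WalkConfig,
    folds: int = 5,
    min_mirnas: int = 5,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Pooled CV AUC over a (λ, η) grid, one shared fold partition.

    Reusing the same rng_seed for every cell means differences across the
    grid reflect the parameters, not fold noise.
    """
    grid = pd.DataFrame(index=lambdas, columns=etas, dtype=float)
    grid.index.name = "lambda"
    grid.columns.name = "eta"
    for lam in lambdas:
        for eta in etas:
            cell_cfg = WalkConfig(
                alpha=config.alpha, lam=lam, eta=eta,
                tol=config.tol, max_iter=config.max_iter, knn_k=config.knn_k,
            )
            res = cross_validate(
                mfsn, dpn, associations, cell_cfg,
                folds=folds, min_mirnas=min_mirnas, rng_seed=rng_seed,
            )
            grid.loc[lam, eta] = res.pooled_auc
    return grid


def rwrmda_baseline(
    mfsn: MultigraphMFSN, seed_mirnas: set[str] | frozenset[str], config: WalkConfig
) -> list[tuple[str, float]]:
    """Single-network baseline: restart walk on the miRNA multigraph only.

    Seeds are the disease's known miRNAs with uniform initial mass; the
    disease network and association bridge are unused, so this method is
    inapplicable to a disease without known miRNAs (empty seed set is an
    error).
    """
    if not seed_mirnas:
        raise ValueError(
            "single-network baseline needs at least one seed miRNA: "
            "it is not applicable to diseases without known related miRNAs"
        )
    for s in seed_mirnas:
        if s not in mfsn.nodes:
            raise KeyError(f"seed miRNA {s!r} not in the miRNA network")
    m = len(mfsn.nodes)
    P0 = np.zeros(m)
    for s in seed_mirnas:
        P0[mfsn.nodes.position(s)] = 1.0 / len(seed_mirnas)
    res = rwr_iterate(mfsn.A, P0, config.alpha, tol=config.tol, max_iter=config.max_iter)
    out = [
        (ident, float(res.P_inf[i]))
        for i, ident in enumerate(mfsn.nodes.ids)
        if ident not in seed_mirnas
    ]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def sample_dropout(
    associations: AssociationSet, fraction: float, rng: np.random.Generator
) -> AssociationSet:
    """Remove round(fraction x |pairs|) association pairs uniformly at random."""
    if not 0 <= fraction < 1:
        raise ValueError("dropout fraction must lie in [0, 1)")
    all_pairs = sorted(associations.pairs)
    n_remove = int(round(fraction * len(all_pairs)))
    if not n_remove:
        return associations
    removed = {
        all_pairs[i] for i in rng.choice(len(all_pairs), size=n_remove, replace=False)
    }
    return associations.without(removed)


def association_dropout(
    mfsn: MultigraphMFSN,
    dpn: PhenotypeNetwork,
    associations: AssociationSet,
    config: WalkConfig,
    fractions: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
    folds: int = 5,
    min_mirnas: int = 5,
    rng_seed: int = 0,
) -> dict[float, float]:
    """Pooled CV AUC after randomly deleting a fraction of associations.

    round(fraction x |pairs|) pairs are removed uniformly at random
    before cross-validation; fraction 0 reproduces the plain CV result.
    """
    rng = np.random.default_rng(rng_seed)
    out: dict[float, float] = {}
    for frac in fractions:
        reduced = sample_dropout(associations, frac, rng)
        res = cross_validate(
            mfsn, dpn, reduced, config,
            folds=folds, min_mirnas=min_mirnas, rng_seed=rng_seed,
        )
        out[frac] = res.pooled_auc
    return out
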