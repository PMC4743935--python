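"""Disease-specific candidate prioritisation from the stationary vector.

After the walk converges, the miRNA-block slice u∞ scores every miRNA by
its proximity to the seed set; candidates — all miRNAs without a known
association to the query disease — are returned in descending score
order.  Seed miRNAs are excluded: they are the input, not a prediction.
"""

from __future__ import annotations

import logging

import numpy as np

from .chn import CHNModel, SeedSet, WalkConfig, build_initial_vector
from .rwr import rwr_iterate

logger = logging.getLogger("chnmird")

__all__ = ["rank_candidates"]


def rank_candidates(
    model: CHNModel, config: WalkConfig, seeds: SeedSet
) -> list[tuple[str, float]]:
    """Rank non-seed miRNAs by stationary walk probability.

    Returns (miRNA, score) pairs sorted by descending u∞ with ties broken
    by ascending miRNA identifier, so equal-score candidates order
    deterministically.
    """
    P0 = build_initial_vector(seeds, config.eta, model.mirna_index, model.disease_index)
    result = rwr_iterate(
        model.M, P0, config.alpha, tol=config.tol, max_iter=config.max_iter,
        m_split=model.m,
    )
    u = result.u_inf
    candidates = [
        (ident, float(u[i]))
        for i, ident in enumerate(model.mirna_index.ids)
        if ident not in seeds.seed_mirnas
    ]
    if not candidates:
        logger.warning("all miRNAs are seeds; empty ranking")
        return []
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return candidates
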