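# Methods

## The prediction model

The method treats miRNA–disease prioritisation as proximity search on a
coupled two-layer system. Its assumptions, in order of importance:

1. **Guilt by functional association.** miRNAs act through their target
   mRNAs, so miRNAs with functionally similar target sets tend to be
   involved in the same diseases. The miRNA side of the system is a
   weighted functional-similarity network over miRNAs.
2. **Phenotype similarity mirrors molecular overlap.** Diseases with
   similar clinical phenotype descriptions tend to share molecular
   causes; the disease side is a K-nearest-neighbour graph over a
   phenotype similarity matrix (scores in [0, 1] computed upstream by
   text mining; this package consumes them).
3. **Known associations transfer information between the sides.** The
   bipartite incidence C of curated miRNA–disease associations couples
   the two networks; a walker crosses it with jumping probability λ.

A random walk with restart from the disease's known miRNAs and the
disease itself converges to a stationary distribution; the miRNA block
u∞ scores every candidate. The restart term guarantees a unique fixed
point (the spectral radius of (1−α)Mᵀ is at most 1−α < 1) and keeps the
walker anchored near the seeds.

### Multigraph integration

Several similarity layers (different data sources) are merged as a
multigraph rather than by averaging weights: each layer is
row-normalised *on its own node set* first, and node i's outgoing row is
the mean of its rows in the Nᵢ layers that contain it. This models a
walker that first picks one of the available evidence sources uniformly,
then steps within it — so a layer's weight scale never dominates, and a
miRNA missing from one source is simply not averaged over it. A node
that belongs to a layer's node set but has no edges there contributes a
zero row, which dilutes its outgoing mass below 1; this is logged. For
layers read from edge lists the case cannot arise (membership is defined
by appearing in an edge), but programmatically built layers can exhibit
it, and the substochastic row is accepted rather than silently
renormalised because the mass loss is informative.

### Transition-matrix edge cases

Literal application of the block rules leaves two degenerate cases the
formulas do not address:

* a node with association links but an empty within-block row would emit
  total mass λ per step; its cross-block row is rescaled to sum to 1
  (logged), keeping M stochastic;
* a node isolated in both blocks keeps an all-zero row; restart mass
  prevents the walk from trapping there, and the per-step mass loss is
  logged.

A disease with no known miRNAs is handled by the initial vector: with an
empty seed-miRNA set, P₀ places full mass on the disease block. Because
the fixed point is linear in P₀, any positive rescaling of P₀ changes no
ranking, so the choice of total mass 1 is presentational.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| α | restart probability | 0.7 | walk-scale mixing; rankings known to be robust to it |
| λ | jumping probability between networks | 0.5 | performance is flat for λ ≥ 0.5, degrades for small λ |
| η | initial-mass share of the disease block | 0.5 | small effect; only reweights seeds |
| K | phenotype KNN neighbour count | 5 | 3–7 give near-identical results |
| tol | L1 convergence threshold | 1e−10 | iteration error far below ranking resolution |
| max_iter | iteration cap | 10 000 | turns non-convergence into a diagnosable error |

All parameters are dimensionless. Ties (equal similarity in KNN
selection, equal stationary scores in rankings) break by ascending
identifier, so every output is reproducible byte for byte.

## Evaluation protocol

**Cross-validation.** Per disease with ≥ 5 known miRNAs, the known set is
shuffled (seeded) and dealt round-robin into 5 folds. For each fold the
held-out pairs are removed from C *before* the network is assembled —
this is asserted programmatically, and a regression test demonstrates
that skipping the removal inflates the AUC to ≈ 1. Candidates for a test
case are all miRNAs not currently known-associated with the disease
(which includes the held-out ones by construction).

**ROC construction.** Each test case reduces to its normalised rank
x = (rank−1)/(n_candidates−1). Sweeping a rank-fraction cutoff t gives
TPR(t) = fraction of cases with x ≤ t, and a cutoff admitting the top
fraction t of a candidate list admits the fraction t of its
non-associated candidates, so FPR(t) = t. The swept area equals the mean
of (n_candidates − rank)/(n_candidates − 1); both routes are implemented
and cross-checked against each other (and against a conventional binary
ROC on single cases). Pooling over all test cases gives the headline
AUC; per-disease AUCs use that disease's cases only.

**Randomization null.** Every disease's column of C is replaced by an
equal-size uniformly random decoy set, and the CV protocol runs
unchanged against the real held-out miRNAs. Decoys for the query disease
exclude only the currently tested fold (a test miRNA drawn as a seed
could not be ranked). Drawing decoys from *all* miRNAs, rather than from
the disease's non-associated candidates, is deliberate: on densely
associated data the candidates-only pool systematically avoids the test
miRNA's neighbourhood and biases the null AUC below 0.5, defeating its
purpose as a no-signal control. On sparse real data the two readings
nearly coincide.

**Leave-one-disease-out.** Every association of the query disease is
deleted, the disease alone seeds the walk, and known miRNAs recovered in
the top N are counted — the regime of a disease with no known miRNAs,
where single-network baselines are inapplicable (the shipped
RWRMDA-style baseline, the same restart walk on the miRNA multigraph
alone, raises an explicit error there).

**Robustness.** `association_dropout` deletes round(fraction·|pairs|)
pairs uniformly at random before CV; `parameter_sweep` re-runs CV over a
(λ, η) grid with one shared fold partition so grid differences reflect
parameters, not fold noise.

## Synthetic study conditions

The generator plants matched miRNA/disease modules: 60 miRNAs and 20
diseases in 4 modules, observed through 3 similarity layers. Pairwise
similarities are truncated Gaussians (within modules 0.60 ± 0.12,
between 0.12 ± 0.08, clipped to [0, 1]); associations are Bernoulli with
probability 0.6 between matched modules and 0.02 elsewhere, and 20 % of
drawn pairs are withheld as recovery truth. These sizes keep a full CV
run (~100 network assemblies and walks) under a tenth of a second while
leaving every disease ~10 known miRNAs, enough for 5 folds; the
within/between separation is wide enough that module recovery is clearly
above chance but noisy enough that held-out ranks are not trivially 1.

What the generator does *not* emulate: heavy-tailed association degree
distributions (real databases are dominated by a few intensively studied
cancers), incomplete layer coverage (real sources miss different miRNA
subsets), correlated noise between layers derived from shared target
data, and name-level curation problems. Passing tests therefore show the
machinery recovers planted block structure under truncated-Gaussian
noise — not that any particular real dataset reaches a particular AUC.

## Numerical choices

* Iterative solver and an independent direct solve (I − (1−α)Mᵀ)P = αP₀
  coexist; tests require L1 agreement ≤ 1e−8 on random networks.
* Dense arrays below 1024 nodes, CSR above; representation changes
  results by < 1e−12 and is therefore invisible in the contract.
* Similarity matrices are symmetrised by averaging on read, warning above
  an asymmetry of 1e−9.
* Association incidence is strictly 0/1; duplicate pairs collapse with a
  warning, conflicting duplicate edge weights are an error.

## Known limitations

* Phenotype similarity and gene-set similarity are consumed, not
  computed; the shipped Jaccard / best-match-average gene-set measures
  are reference implementations for synthetic work, not reproductions of
  any published PPI- or GO-based scoring tool.
* The walk treats C as binary; evidence strength or recency is ignored.
* Diseases absent from the phenotype matrix and miRNAs absent from every
  similarity layer cannot be ranked (they have no node).
* Pooled AUC weights every test case equally, so heavily annotated
  diseases dominate the headline number; per-disease tables are reported
  alongside for that reason.
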