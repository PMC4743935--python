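import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from chnmird.chn import WalkConfig
from chnmird.evaluation import (
    association_dropout,
    cross_validate,
    loo_disease_topn,
    mean_percentile_auc,
    parameter_sweep,
    randomization_test,
    rank_auc,
    roc_points,
    rwrmda_baseline,
    sample_dropout,
)
from chnmird.ranking import rank_candidates
from chnmird.chn import SeedSet, build_transition
from chnmird.core_io import AssociationSet, NodeIndex
from chnmird.multigraph import row_normalize


class TestRankAUC:
    def test_perfect_ranking_gives_auc_one(self):
        assert rank_auc([(1, 50)] * 10 + [(1, 7)] * 3) == pytest.approx(1.0)

    def test_uniform_ranks_give_auc_half(self):
        rng = np.random.default_rng(0)
        n_cand = 100
        ranks = [(int(r), n_cand) for r in rng.integers(1, n_cand + 1, size=4000)]
        assert rank_auc(ranks) == pytest.approx(0.5, abs=0.02)

    def test_enumerated_three_case_example(self):
        ranks = [(1, 4), (2, 4), (3, 4)]
        # closed form: mean of (3/3, 2/3, 1/3) = 2/3
        assert mean_percentile_auc(ranks) == pytest.approx(2 / 3)
        assert rank_auc(ranks) == pytest.approx(2 / 3)

    def test_sweep_equals_closed_form_on_random_lists(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            k = int(rng.integers(1, 40))
            ranks = []
            for _ in range(k):
                n = int(rng.integers(2, 300))
                ranks.append((int(rng.integers(1, n + 1)), n))
            assert rank_auc(ranks) == pytest.approx(mean_percentile_auc(ranks), abs=1e-12)

    def test_single_case_matches_binary_roc_oracle(self):
        # one test case = one positive among its candidate list; the
        # rank-threshold AUC must agree with a conventional ROC on that list
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(3, 50))
            r = int(rng.integers(1, n + 1))
            labels = np.zeros(n)
            labels[r - 1] = 1
            scores = -np.arange(n)  # rank 1 has the highest score
            assert rank_auc([(r, n)]) == pytest.approx(
                roc_auc_score(labels, scores)
            )

    def test_pooled_auc_lies_between_parts(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = [(int(rng.integers(1, 21)), 20) for _ in range(int(rng.integers(1, 10)))]
            b = [(int(rng.integers(1, 51)), 50) for _ in range(int(rng.integers(1, 10)))]
            lo, hi = sorted([rank_auc(a), rank_auc(b)])
            assert lo - 1e-12 <= rank_auc(a + b) <= hi + 1e-12

    def test_invalid_ranks_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            rank_auc([(5, 4)])
        with pytest.raises(ValueError, match="at least one"):
            rank_auc([])

    def test_roc_polyline_is_monotone(self):
        pts = roc_points([(1, 4), (2, 4), (4, 4), (2, 10)])
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)


class TestCrossValidation:
    def test_planted_structure_is_recovered(self, networks, config):
        mfsn, dpn, assoc = networks
        res = cross_validate(mfsn, dpn, assoc, config, rng_seed=1)
        assert res.pooled_auc > 0.7
        assert all(1 <= c.rank <= c.n_candidates for c in res.cases)

    def test_fixed_seed_is_reproducible(self, networks, config):
        mfsn, dpn, assoc = networks
        a = cross_validate(mfsn, dpn, assoc, config, rng_seed=5)
        b = cross_validate(mfsn, dpn, assoc, config, rng_seed=5)
        assert a == b
        c = cross_validate(mfsn, dpn, assoc, config, rng_seed=6)
        assert a.cases != c.cases

    def test_leaving_held_out_pairs_in_c_leaks(self, networks, config):
        """Held-out pairs left inside C let the walk see the answer."""
        mfsn, dpn, assoc = networks
        clean = cross_validate(mfsn, dpn, assoc, config, rng_seed=1)
        leaky = cross_validate(
            mfsn, dpn, assoc, config, rng_seed=1, leak_held_out=True
        )
        assert leaky.pooled_auc > 0.95
        assert leaky.pooled_auc > clean.pooled_auc

    def test_per_disease_aucs_pool_consistently(self, networks, config):
        mfsn, dpn, assoc = networks
        res = cross_validate(mfsn, dpn, assoc, config, rng_seed=2)
        lo = min(res.per_disease_auc.values())
        hi = max(res.per_disease_auc.values())
        assert lo - 1e-12 <= res.pooled_auc <= hi + 1e-12

    def test_no_eligible_disease_rejected(self, networks, config):
        mfsn, dpn, assoc = networks
        with pytest.raises(ValueError, match="no disease"):
            cross_validate(mfsn, dpn, assoc, config, min_mirnas=10_000)


def test_randomization_null_carries_no_signal(networks, config):
    mfsn, dpn, assoc = networks
    aucs = randomization_test(mfsn, dpn, assoc, config, n_reps=5, rng_seed=7)
    assert len(aucs) == 5
    assert 0.35 < float(np.mean(aucs)) < 0.65
    again = randomization_test(mfsn, dpn, assoc, config, n_reps=5, rng_seed=7)
    assert aucs == again  # fixed seed reproducibility


class TestLeaveOneDiseaseOut:
    def test_counts_nest_and_saturate(self, networks, config):
        mfsn, dpn, assoc = networks
        m_total = len(mfsn.nodes)
        counts = loo_disease_topn(
            mfsn, dpn, assoc, config, n_list=(1, 5, 10, 20, 50, m_total)
        )
        values = [counts[N] for N in (1, 5, 10, 20, 50, m_total)]
        assert values == sorted(values)  # non-decreasing in N
        assert counts[m_total] == len(assoc)  # top-all recovers everything

    def test_planted_seeding_beats_random_disease_seeding(self, networks, config):
        """Top-1 recovery from the true disease seed must exceed the
        permutation null where the seeded disease is scrambled."""
        mfsn, dpn, assoc = networks
        real = loo_disease_topn(mfsn, dpn, assoc, config, n_list=(5,))[5]
        rng = np.random.default_rng(0)
        diseases = list(assoc.diseases)
        null_counts = []
        for _ in range(5):
            perm = rng.permutation(len(diseases))
            remap = {diseases[i]: diseases[perm[i]] for i in range(len(diseases))}
            shuffled = AssociationSet(
                frozenset((m, remap[d]) for m, d in assoc.pairs)
            )
            null_counts.append(
                loo_disease_topn(mfsn, dpn, shuffled, config, n_list=(5,))[5]
            )
        assert real > max(null_counts)


class TestParameterSweep:
    def test_grid_shape_and_consistency(self, networks, config):
        mfsn, dpn, assoc = networks
        grid = parameter_sweep(
            mfsn, dpn, assoc, [0.3, 0.5], [0.4, 0.6], config, rng_seed=4
        )
        assert grid.shape == (2, 2)
        assert np.all((grid.values >= 0) & (grid.values <= 1))
        # shared partition: the (0.5, eta=0.5-ish) cell replays cross_validate
        ref = cross_validate(
            mfsn, dpn, assoc,
            WalkConfig(alpha=config.alpha, lam=0.5, eta=0.4), rng_seed=4,
        )
        assert grid.loc[0.5, 0.4] == pytest.approx(ref.pooled_auc)


class TestSingleNetworkBaseline:
    def test_empty_seed_set_is_an_explicit_error(self, networks, config):
        mfsn, _, _ = networks
        with pytest.raises(ValueError, match="not applicable"):
            rwrmda_baseline(mfsn, set(), config)

    def test_deterministic_given_inputs(self, networks, config):
        mfsn, _, assoc = networks
        seeds = set(list(assoc.mirnas)[:5])
        assert rwrmda_baseline(mfsn, seeds, config) == rwrmda_baseline(
            mfsn, seeds, config
        )

    def test_equals_chn_ranking_when_association_bridge_is_empty(self, networks, config):
        """With C empty the heterogeneous walk decouples: its miRNA block
        reduces to the single-network walk up to the constant (1-eta)."""
        mfsn, dpn, _ = networks
        C = np.zeros((len(mfsn.nodes), len(dpn.nodes)))
        model = build_transition(mfsn.A, dpn.B, C, config.lam, mfsn.nodes, dpn.nodes)
        seed_mirnas = frozenset(list(mfsn.nodes.ids)[:4])
        seeds = SeedSet(seed_mirnas, frozenset({dpn.nodes.ids[0]}))
        chn_ranking = rank_candidates(model, config, seeds)
        base_ranking = rwrmda_baseline(mfsn, set(seed_mirnas), config)
        assert [m for m, _ in chn_ranking] == [m for m, _ in base_ranking]
        for (m1, s1), (m2, s2) in zip(chn_ranking, base_ranking):
            assert s1 == pytest.approx((1 - config.eta) * s2, abs=1e-9)


class TestAssociationDropout:
    def test_removed_count_follows_the_rounding_rule(self, networks):
        _, _, assoc = networks
        rng = np.random.default_rng(0)
        for frac in (0.0, 0.05, 0.17, 0.30):
            reduced = sample_dropout(assoc, frac, rng)
            assert len(assoc) - len(reduced) == int(round(frac * len(assoc)))
            assert reduced.pairs <= assoc.pairs

    def test_zero_fraction_reproduces_plain_cv(self, networks, config):
        mfsn, dpn, assoc = networks
        out = association_dropout(
            mfsn, dpn, assoc, config, fractions=(0.0,), rng_seed=3
        )
        ref = cross_validate(mfsn, dpn, assoc, config, rng_seed=3)
        assert out[0.0] == pytest.approx(ref.pooled_auc)

    def test_recovery_degrades_slowly_under_dropout(self, networks, config):
        """Deleting up to 30% of associations costs little accuracy
        (median over replicates)."""
        mfsn, dpn, assoc = networks
        deltas = []
        for seed in range(5):
            out = association_dropout(
                mfsn, dpn, assoc, config, fractions=(0.0, 0.30), rng_seed=seed
            )
            deltas.append(out[0.0] - out[0.30])
        assert float(np.median(deltas)) < 0.1
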