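"""Query weighting, pseudo-count aggregation, ranking, and CV scheme selection."""

import math

import numpy as np
import pytest

import workuprec as w
from workuprec.errors import ColdStartError, ConfigurationError
from workuprec.recommender import SCHEME_NAMES

from conftest import L1, L2, X, Y, episode, item


@pytest.fixture
def toy_background(toy_matrix):
    # outside prevalences chosen so RR_X = 2 and RR_Y = 6 (cohort prev 3/5)
    n_outside = 1000
    counts = {
        X: toy_matrix.query_counts[X] + int(0.3 * n_outside),
        Y: toy_matrix.query_counts[Y] + int(0.1 * n_outside),
    }
    return w.BackgroundStats(n_outpt=n_outside + 5, outpt_counts=counts)


class TestItemWeight:
    def test_uniform_is_one(self, toy_matrix, toy_background):
        s = w.WeightingScheme(name="uniform")
        assert w.item_weight(s, toy_matrix, toy_background, X) == 1.0

    def test_inverse_frequency_log_form(self, toy_matrix, toy_background):
        s = w.WeightingScheme(name="inverse_frequency")
        assert w.item_weight(s, toy_matrix, toy_background, X) == pytest.approx(
            1.0 / math.log(1 + 3)
        )

    def test_inverse_frequency_linear_form(self, toy_matrix, toy_background):
        s = w.WeightingScheme(name="inverse_frequency", inverse_form="linear")
        assert w.item_weight(s, toy_matrix, toy_background, X) == pytest.approx(1 / 3)

    def test_relative_risk_and_combined(self, toy_matrix, toy_background):
        rr = w.item_weight(w.WeightingScheme(name="relative_risk"),
                           toy_matrix, toy_background, X)
        assert rr == pytest.approx(2.0)
        combined = w.item_weight(w.WeightingScheme(name="combined"),
                                 toy_matrix, toy_background, X)
        assert combined == pytest.approx(2.0 / math.log(4))

    def test_unknown_item_weighs_zero(self, toy_matrix, toy_background):
        for name in SCHEME_NAMES:
            s = w.WeightingScheme(name=name)
            assert w.item_weight(s, toy_matrix, toy_background, item("ghost")) == 0.0

    def test_weights_nonnegative_under_every_scheme(self, toy_matrix, toy_background):
        for name in SCHEME_NAMES:
            s = w.WeightingScheme(name=name)
            for a in toy_matrix.query_counts:
                assert w.item_weight(s, toy_matrix, toy_background, a) >= 0.0


class TestAggregateScores:
    def test_single_item_reduces_to_ppv_column(self, toy_matrix, toy_background):
        scores = w.aggregate_scores({X}, toy_matrix, toy_background,
                                    w.WeightingScheme(name="uniform"))
        assert scores[L1] == pytest.approx(w.ppv(toy_matrix, X, L1))
        assert scores[L2] == pytest.approx(w.ppv(toy_matrix, X, L2))

    def test_toy_two_item_query_sums(self, toy_matrix, toy_background):
        scores = w.aggregate_scores({X, Y}, toy_matrix, toy_background,
                                    w.WeightingScheme(name="uniform"))
        assert scores[L1] == pytest.approx(4 / 3)
        assert scores[L2] == pytest.approx(2 / 3)

    def test_linearity_under_identical_profiles(self):
        # two query items with identical PPV profiles double the scores
        a1, a2 = item("A1"), item("A2")
        eps = [episode(f"P{i}", {a1, a2}, {L1} if i < 3 else {L2}) for i in range(5)]
        m = w.build_matrix(eps)
        s1 = w.aggregate_scores({a1}, m, None, w.WeightingScheme(name="uniform"))
        s12 = w.aggregate_scores({a1, a2}, m, None, w.WeightingScheme(name="uniform"))
        for b in (L1, L2):
            assert s12[b] == pytest.approx(2 * s1[b])

    def test_out_of_vocabulary_query_is_cold_start(self, toy_matrix, toy_background):
        with pytest.raises(ColdStartError):
            w.aggregate_scores({item("ghost")}, toy_matrix, toy_background,
                               w.WeightingScheme(name="uniform"))


class TestRecommend:
    def test_toy_query_x_ranks_l1_first(self, toy_matrix, toy_background):
        recs = w.recommend({X}, toy_matrix, toy_background,
                           w.WeightingScheme(name="uniform"), k=2)
        assert [e.item for e in recs.entries] == [L1, L2]
        assert not recs.fallback_used
        assert recs.entries[0].ppv == pytest.approx(1.0)
        assert recs.entries[0].endocrine_prevalence == pytest.approx(3 / 5)

    def test_k_beyond_candidates_returns_full_list(self, toy_matrix, toy_background):
        recs = w.recommend({X}, toy_matrix, toy_background, k=50)
        assert len(recs.entries) == len(toy_matrix.targets)

    def test_cold_start_falls_back_to_prevalence(self, toy_matrix, toy_background):
        recs = w.recommend({item("ghost")}, toy_matrix, toy_background, k=2)
        assert recs.fallback_used
        assert [e.item for e in recs.entries] == [L1, L2]  # prevalence 3/5 > 2/5

    def test_single_query_uniform_reproduces_ppv_ranking(self, benchmark):
        m, bg = benchmark.matrix, benchmark.background
        a = item("hypothyroidism")
        recs = w.recommend({a}, m, bg, w.WeightingScheme(name="uniform"),
                           k=len(m.targets))
        ppvs = [w.ppv(m, a, e.item) for e in recs.entries]
        assert ppvs == sorted(ppvs, reverse=True)
        assert recs.entries[0].ppv == pytest.approx(max(w.ppv(m, a, b) for b in m.targets))

    def test_ranking_invariant_to_weight_scale(self, benchmark):
        m, bg = benchmark.matrix, benchmark.background
        ep = next(e for e in benchmark.test if e.query_items and e.target_items)
        base = w.recommend(ep, m, bg, w.WeightingScheme(name="combined"), k=10)
        scaled = w.recommend(ep, m, bg, w.WeightingScheme(name="combined", scale=7.3), k=10)
        assert [e.item for e in base.entries] == [e.item for e in scaled.entries]

    def test_score_monotone_in_pair_count(self, toy_matrix, toy_background):
        """Raising N_AB (all else fixed) never lowers B's rank for queries with A."""
        boosted = w.AssociationMatrix(
            n_cohort=toy_matrix.n_cohort,
            query_counts=dict(toy_matrix.query_counts),
            target_counts=dict(toy_matrix.target_counts),
            pair_counts={**toy_matrix.pair_counts, (X, L2): 2},
        )
        before = [e.item for e in w.recommend({X}, toy_matrix, toy_background, k=2).entries]
        after = [e.item for e in w.recommend({X}, boosted, toy_background, k=2).entries]
        assert before.index(L2) >= after.index(L2)

    def test_untrained_matrix_rejected(self, toy_background):
        empty = w.AssociationMatrix(n_cohort=0, query_counts={}, target_counts={}, pair_counts={})
        with pytest.raises(w.errors.UntrainedModelError):
            w.recommend({X}, empty, toy_background)

    def test_tie_break_by_prevalence_then_concept(self):
        # two targets unseen for the query score 0; prevalence then name decide
        a, z = item("A"), item("Z")
        t_hi = item("t_common", "measurement")
        t_lo = item("a_rare", "measurement")
        eps = [episode("P1", {a}, {t_hi}), episode("P2", {z}, {t_hi}),
               episode("P3", {z}, {t_lo})]
        m = w.build_matrix(eps)
        recs = w.recommend({a}, m, None, w.WeightingScheme(name="uniform"), k=3)
        assert [e.item for e in recs.entries][:1] == [t_hi]
        # both remaining candidates for Z-queries: prevalence ranks t_hi first overall


class TestSelectWeighting:
    def test_same_seed_reproduces_folds_and_table(self, benchmark):
        train = benchmark.train[:300]
        best1, t1 = w.select_weighting(train, benchmark.background, n_folds=5, seed=9)
        best2, t2 = w.select_weighting(train, benchmark.background, n_folds=5, seed=9)
        assert best1 == best2 and t1 == t2

    def test_degenerate_tie_broken_by_scheme_order(self, toy_background):
        eps = [episode(f"P{i}", {X}, {L1}) for i in range(10)]
        best, table = w.select_weighting(eps, toy_background, n_folds=2, seed=0)
        means = {v["mean_precision_at_k"] for v in table.values()}
        assert len(means) == 1  # all schemes identical on degenerate data
        assert best.name == "uniform"  # first in documented candidate order

    def test_fewer_episodes_than_folds_rejected(self, toy_episodes, toy_background):
        with pytest.raises(ConfigurationError):
            w.select_weighting(toy_episodes, toy_background, n_folds=10)
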