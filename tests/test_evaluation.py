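"""Top-k metrics, pooled ROC AUC, bootstrap intervals, baselines, comparisons."""

import numpy as np
import pytest

import workuprec as w
from workuprec.errors import UndefinedMetricError

from conftest import L1, L2, X, episode, item
from oracles import pairwise_auc


def _items(names):
    return [item(n, "measurement") for n in names]


class TestPrecisionRecallAtK:
    def test_half_precision_two_thirds_recall(self):
        rec = _items(["a", "b", "c", "d"])
        actual = set(_items(["a", "c", "e"]))
        p, r = w.precision_recall_at_k(rec, actual, k=4)
        assert p == pytest.approx(0.5)
        assert r == pytest.approx(2 / 3)

    def test_perfect_top_k(self):
        rec = _items(["a", "b", "c", "d"])
        p, r = w.precision_recall_at_k(rec, set(rec), k=4)
        assert (p, r) == (1.0, 1.0)

    def test_short_list_keeps_fixed_k_denominator(self):
        rec = _items(["a", "b"])
        p, _ = w.precision_recall_at_k(rec, set(_items(["a", "z"])), k=4)
        assert p == pytest.approx(0.25)

    def test_only_top_k_counts(self):
        rec = _items(["m1", "m2", "m3", "m4", "hit"])
        p, r = w.precision_recall_at_k(rec, set(_items(["hit"])), k=4)
        assert (p, r) == (0.0, 0.0)

    def test_empty_actual_set_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            w.precision_recall_at_k(_items(["a"]), set(), k=4)


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        cands = _items(["a", "b", "c", "d"])
        scores = [{cands[0]: 9.0, cands[1]: 8.0, cands[2]: 0.1, cands[3]: 0.2}]
        actuals = [set(cands[:2])]
        assert w.roc_auc(scores, actuals, cands) == 1.0

    def test_midrank_tie_hand_value(self):
        # positives scored {3, 2}, negatives {2, 1}: AUC = 3.5/4 = 0.875
        cands = _items(["a", "b", "c", "d"])
        scores = [dict(zip(cands, [3.0, 2.0, 2.0, 1.0]))]
        actuals = [set(cands[:2])]
        assert w.roc_auc(scores, actuals, cands) == pytest.approx(0.875)

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        cands = _items([f"t{i}" for i in range(12)])
        for _ in range(100):
            scores = {c: float(rng.integers(0, 5)) for c in cands}
            actual = {c for c in cands if rng.random() < 0.4}
            if not 0 < len(actual) < len(cands):
                continue
            ours = w.roc_auc([scores], [actual], cands)
            labels = [c in actual for c in cands]
            vals = [scores[c] for c in cands]
            assert ours == pytest.approx(pairwise_auc(vals, labels), abs=1e-12)

    def test_label_permutation_averages_to_half(self):
        rng = np.random.default_rng(5)
        cands = _items([f"t{i}" for i in range(20)])
        scores = {c: float(rng.random()) for c in cands}
        aucs = []
        for _ in range(200):
            labels = rng.permutation([True] * 6 + [False] * 14)
            actual = {c for c, lab in zip(cands, labels) if lab}
            aucs.append(w.roc_auc([scores], [actual], cands))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_single_class_is_undefined(self):
        cands = _items(["a", "b"])
        with pytest.raises(UndefinedMetricError):
            w.roc_auc([{c: 1.0 for c in cands}], [set(cands)], cands)

    def test_per_episode_averaging_flag(self):
        cands = _items(["a", "b"])
        scores = [{cands[0]: 2.0, cands[1]: 1.0}, {cands[0]: 1.0, cands[1]: 2.0}]
        actuals = [{cands[0]}, {cands[0]}]
        assert w.roc_auc(scores, actuals, cands, per_episode=True) == pytest.approx(0.5)


class TestBootstrapCI:
    def test_constant_metric_collapses_to_point(self):
        point, lo, hi = w.bootstrap_ci(lambda xs: 0.7, list(range(30)),
                                       n_resamples=100, seed=1)
        assert (point, lo, hi) == (0.7, 0.7, 0.7)

    def test_seed_determinism(self):
        data = list(np.random.default_rng(0).normal(size=50))
        ci1 = w.bootstrap_ci(lambda xs: float(np.mean(xs)), data, n_resamples=200, seed=4)
        ci2 = w.bootstrap_ci(lambda xs: float(np.mean(xs)), data, n_resamples=200, seed=4)
        ci3 = w.bootstrap_ci(lambda xs: float(np.mean(xs)), data, n_resamples=200, seed=5)
        assert ci1 == ci2
        assert ci1 != ci3

    def test_interval_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(8)
        small = list(rng.normal(size=200))
        large = list(rng.normal(size=2000))
        mean = lambda xs: float(np.mean(xs))
        _, lo_s, hi_s = w.bootstrap_ci(mean, small, n_resamples=300, seed=2)
        _, lo_l, hi_l = w.bootstrap_ci(mean, large, n_resamples=300, seed=2)
        assert (hi_l - lo_l) < (hi_s - lo_s)

    def test_undefined_resample_redrawn(self):
        calls = {"n": 0}

        def flaky(xs):
            calls["n"] += 1
            if calls["n"] % 7 == 3:
                raise UndefinedMetricError("synthetic failure")
            return float(np.mean(xs))

        point, lo, hi = w.bootstrap_ci(flaky, list(range(20)), n_resamples=50, seed=3)
        assert lo <= point <= hi


class TestBaselines:
    def test_endocrine_prevalence_is_query_independent(self, toy_matrix):
        ranker = w.baseline_ranker("endocrine_prevalence", toy_matrix)
        ep1 = episode("P1", {X}, {L1})
        ep2 = episode("P2", {item("other")}, {L2})
        assert ranker.ranked_items(ep1) == ranker.ranked_items(ep2)

    def test_toy_prevalence_order(self, toy_matrix):
        ranker = w.baseline_ranker("endocrine_prevalence", toy_matrix)
        assert ranker.ranked_items(episode("P", {X}, {L1})) == [L1, L2]

    def test_outpatient_prevalence_uses_background(self, toy_matrix):
        bg = w.BackgroundStats(n_outpt=100, outpt_counts={L1: 5, L2: 50})
        ranker = w.baseline_ranker("outpatient_prevalence", toy_matrix, bg)
        assert ranker.ranked_items(episode("P", {X}, {L1})) == [L2, L1]

    def test_random_ranker_reproducible_for_fixed_seed(self, toy_matrix):
        eps = [episode(f"P{i}", {X}, {L1}) for i in range(5)]
        r1 = w.baseline_ranker("random", toy_matrix, seed=11)
        r2 = w.baseline_ranker("random", toy_matrix, seed=11)
        order1 = [r1.ranked_items(ep) for ep in eps]
        order2 = [r2.ranked_items(ep) for ep in eps]
        assert order1 == order2


class TestCompareRankers:
    def test_ranker_against_itself(self, benchmark):
        ranker = w.baseline_ranker("endocrine_prevalence", benchmark.matrix)
        delta, _, p = w.compare_rankers(ranker, ranker, benchmark.matrix,
                                        benchmark.test[:100], n_resamples=100, seed=0)
        assert delta == 0.0 and p == 1.0

    def test_argument_swap_negates_delta(self, benchmark):
        m, bg = benchmark.matrix, benchmark.background
        r1 = w.RecommenderRanker(m, bg)
        r2 = w.baseline_ranker("endocrine_prevalence", m)
        eps = benchmark.test[:150]
        d12, _, _ = w.compare_rankers(r1, r2, m, eps, n_resamples=50, seed=1)
        d21, _, _ = w.compare_rankers(r2, r1, m, eps, n_resamples=50, seed=1)
        assert d12 == pytest.approx(-d21)

    def test_recommender_beats_random_with_significance(self, benchmark):
        m, bg = benchmark.matrix, benchmark.background
        r1 = w.RecommenderRanker(m, bg)
        r2 = w.baseline_ranker("random", m, seed=6)
        delta, (lo, hi), p = w.compare_rankers(r1, r2, m, benchmark.test,
                                               n_resamples=500, seed=2)
        assert delta > 0 and lo > 0
        assert p < 0.05


class TestEvaluateRankers:
    def test_report_shape_and_ci_ordering(self, benchmark):
        m, bg = benchmark.matrix, benchmark.background
        rankers = {
            "recommender": w.RecommenderRanker(m, bg),
            "endocrine_prevalence": w.baseline_ranker("endocrine_prevalence", m),
        }
        results = w.evaluate_rankers(rankers, m, benchmark.test[:120],
                                     n_bootstrap=50, seed=3)
        assert set(results) == set(rankers)
        for res in results.values():
            assert res.precision_ci[0] <= res.precision_at_k <= res.precision_ci[1]
            assert res.recall_ci[0] <= res.recall_at_k <= res.recall_ci[1]
            assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]
            assert 0 <= res.auc <= 1

    def test_episodes_without_targets_excluded(self, toy_matrix, caplog):
        rankers = {"endocrine_prevalence": w.baseline_ranker("endocrine_prevalence", toy_matrix)}
        eps = [episode("P1", {X}, {L1}), episode("P2", {X}, set())]
        with caplog.at_level("INFO"):
            results = w.evaluate_rankers(rankers, toy_matrix, eps, n_bootstrap=10, seed=0)
        assert results["endocrine_prevalence"].n_episodes == 1
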