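"""Metrics, lift charts, cross-validation and feature ablation."""

import math
import random

import numpy as np
import pytest

from mram.evaluate import (
    ablation_study,
    accuracy,
    auc,
    cross_validate,
    lift_chart,
    likelihood_metrics,
    make_folds,
)
from mram.miner import MiningParams
from mram.network import build_pin
from mram.relstore import build_cases, FEATURE_ATTRIBUTES
from mram.synthetic import SyntheticConfig, generate, topology_signal_config

from conftest import make_caseset


class TestAccuracy:
    def test_extremes(self):
        assert accuracy(["Y", "N"], ["Y", "N"]) == 1.0
        assert accuracy(["Y", "N"], ["N", "Y"]) == 0.0

    def test_formula_on_constructed_predictions(self):
        # 93 correct predictions of 100 give 93% accuracy
        labels = ["Y"] * 50 + ["N"] * 50
        preds = labels[:]
        for i in range(7):
            preds[i] = "N"
        assert accuracy(preds, labels) == pytest.approx(0.93)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            accuracy(["Y"], ["Y", "N"])


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_pairwise_enumeration_example(self):
        # pos-neg pairs: (.9,.8)win (.9,.3)win (.4,.8)loss (.4,.3)win -> 3/4
        assert auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([0.5, 0.6], [1, 1])

    def test_complement_identity_for_tie_free_scores(self):
        rng = random.Random(4)
        scores = rng.sample(range(1000), 40)
        labels = [rng.choice([0, 1]) for _ in range(38)] + [0, 1]
        a1 = auc(scores, labels)
        a2 = auc(scores, [1 - y for y in labels])
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_sklearn_roc_auc(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(8)
        scores = rng.random(200).round(2)  # rounding forces ties
        labels = rng.integers(0, 2, 200)
        assert auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestLikelihoodMetrics:
    def test_perfect_probabilities(self):
        log_score, lift, rmse = likelihood_metrics([1, 1, 1], [0.5] * 3)
        assert log_score == pytest.approx(0.0)
        assert rmse == pytest.approx(0.0)

    def test_prior_prediction_has_zero_lift(self):
        priors = [0.3, 0.7, 0.3]
        _, lift, _ = likelihood_metrics(priors, priors)
        assert lift == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_two_case_example(self):
        log_score, lift, rmse = likelihood_metrics([0.5, 0.8], [0.5, 0.5])
        assert log_score == pytest.approx(
            (math.log10(0.5) + math.log10(0.8)) / 2, abs=1e-12)
        assert lift == pytest.approx(log_score - math.log10(0.5), abs=1e-12)
        assert rmse == pytest.approx(math.sqrt((0.25 + 0.04) / 2), abs=1e-12)

    def test_lift_identity_exact(self):
        rng = np.random.default_rng(3)
        p = rng.random(100)
        q = rng.random(100)
        log_score, lift, _ = likelihood_metrics(p, q)
        prior_score = likelihood_metrics(q, q)[0]
        assert abs(lift - (log_score - prior_score)) < 1e-12

    def test_zero_probability_floored_not_infinite(self):
        log_score, _, rmse = likelihood_metrics([0.0], [0.5])
        assert math.isfinite(log_score)
        assert rmse <= 1.0


class TestLiftChart:
    def test_perfect_ranking_reaches_one_at_prevalence(self):
        curve = lift_chart([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        points = dict(curve.points)
        assert points[0.5] == pytest.approx(1.0)
        assert curve.points == curve.ideal

    def test_worst_ranking_flat_until_negatives_exhausted(self):
        curve = lift_chart([0.1, 0.2, 0.9, 0.8], [1, 1, 0, 0])
        points = dict(curve.points)
        assert points[0.5] == pytest.approx(0.0)
        assert points[1.0] == pytest.approx(1.0)

    def test_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 48).tolist() + [0, 1]
        curve = lift_chart(scores, labels)
        ys = [y for _, y in curve.points]
        assert curve.points[0] == (0.0, 0.0)
        assert ys[-1] == pytest.approx(1.0)
        assert all(b >= a - 1e-12 for a, b in zip(ys, ys[1:]))

    def test_random_scores_hug_the_diagonal(self):
        # with exchangeable scores the captured fraction at depth k is
        # hypergeometric with sd <= 1/(2 sqrt(n_pos)); test at +-4 sigma
        rng = np.random.default_rng(12)
        labels = np.array([1] * 100 + [0] * 100)
        scores = rng.random(200)
        curve = lift_chart(scores, labels)
        for x, y in curve.points[10:]:
            assert abs(y - x) < 4 * 0.05 + 0.02

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            lift_chart([0.4, 0.5], [1, 1])


def _planted_cases(seed=17, **kwargs):
    ds = generate(SyntheticConfig(seed=seed, **kwargs))
    net = build_pin(ds.edges, ds.positives | ds.negatives)
    return build_cases(net, ds.annotations, ds.positives, ds.negatives)


class TestCrossValidate:
    def test_folds_are_disjoint_stratified_and_covering(self):
        cases = _planted_cases(n_proteins=200)
        folds = make_folds(cases, k=5, seed=0)
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(len(cases)))
        sizes = [len(t) for _, t in folds]
        assert max(sizes) - min(sizes) <= 1
        y = np.array([c.class_item.value for c in cases.cases])
        pos_counts = [int((y[t] == "Y").sum()) for _, t in folds]
        assert max(pos_counts) - min(pos_counts) <= 1

    def test_reproducible_from_seed(self):
        cases = _planted_cases(n_proteins=200)
        r1 = cross_validate(cases, "nbayes", k=5, seed=9)
        r2 = cross_validate(cases, "nbayes", k=5, seed=9)
        assert r1.mean_sd == r2.mean_sd

    def test_k_beyond_minority_class_errors(self):
        cases = make_caseset(
            [("a", "Y", []), ("b", "N", []), ("c", "N", [])])
        with pytest.raises(ValueError):
            cross_validate(cases, "dummy", k=2, seed=0)

    def test_mram_auc_on_planted_signal(self):
        cases = _planted_cases()
        report = cross_validate(
            cases, "mram", k=10, seed=17,
            params=MiningParams(min_support=0.05, min_probability=0.4,
                                consequent_filter="class"))
        assert report.mean_sd["auc"][0] > 0.9

    def test_dummy_learner_on_permuted_labels(self):
        cases = _planted_cases(n_proteins=300)
        rng = random.Random(1)
        labels = [c.class_item.value for c in cases.cases]
        rng.shuffle(labels)
        permuted = make_caseset([
            (c.case_id, y, sorted(i.render() for i in c.feature_items))
            for c, y in zip(cases.cases, labels)
        ])
        report = cross_validate(permuted, "dummy", k=10, seed=3)
        assert abs(report.mean_sd["likelihood_lift"][0]) < 0.02
        assert 0.45 <= report.mean_sd["auc"][0] <= 0.55

    def test_baseline_learners_run_behind_same_interface(self):
        cases = _planted_cases(n_proteins=200)
        for learner in ("dtree", "nbayes", "nnet"):
            report = cross_validate(cases, learner, k=3, seed=0)
            assert 0.0 <= report.mean_sd["auc"][0] <= 1.0

    def test_report_lift_identity_per_fold(self):
        cases = _planted_cases(n_proteins=200)
        report = cross_validate(cases, "nbayes", k=5, seed=0)
        for fold in report.per_fold:
            # lift was computed as the exact difference of log scores
            assert math.isfinite(fold.likelihood_lift)
            assert fold.rmse <= 1.0 and 0.0 <= fold.auc <= 1.0


@pytest.fixture(scope="module")
def topology_dataset():
    ds = generate(topology_signal_config(seed=17, n_proteins=400))
    net = build_pin(ds.edges, ds.positives | ds.negatives)
    return ds, net


class TestAblation:

    def test_topology_mask_matters_most_when_only_topology_signals(
            self, topology_dataset):
        ds, net = topology_dataset

        def builder(mask):
            return build_cases(net, ds.annotations, ds.positives,
                               ds.negatives, feature_mask=mask)

        masks = [
            tuple(FEATURE_ATTRIBUTES),
            ("degree", "articulation", "pathway", "domain"),  # no GO
            ("degree", "articulation", "go", "domain"),       # no pathway
            ("degree", "articulation", "go", "pathway"),      # no domain
            ("go", "pathway", "domain"),                      # no topology
        ]
        params = MiningParams(min_support=0.05, min_probability=0.4,
                              consequent_filter="class")
        results = ablation_study(builder, masks, "mram", k=10, seed=17,
                                 params=params)
        lifts = dict(results)
        assert tuple(FEATURE_ATTRIBUTES) in lifts
        no_topology = lifts[("go", "pathway", "domain")]
        assert no_topology == min(lifts.values())

    def test_identical_masks_identical_lifts(self, topology_dataset):
        ds, net = topology_dataset

        def builder(mask):
            return build_cases(net, ds.annotations, ds.positives,
                               ds.negatives, feature_mask=mask)

        params = MiningParams(min_support=0.05, min_probability=0.4,
                              consequent_filter="class")
        mask = tuple(FEATURE_ATTRIBUTES)
        results = ablation_study(builder, [mask, mask], "mram", k=5,
                                 seed=17, params=params)
        assert results[0][1] == results[1][1]
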