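"""Cost-sensitive model objects: weighting, bagging, CV, serialization."""

import numpy as np
import pandas as pd
import pytest

import abcc2pred as a
from abcc2pred.modeling import LEARNERS, cost_weights, make_learner


@pytest.fixture(scope="module")
def separable():
    """Linearly separable two-class data with a wide margin."""
    rng = np.random.default_rng(7)
    n = 60
    X0 = rng.normal(loc=-2.0, scale=0.3, size=(n, 2))
    X1 = rng.normal(loc=+2.0, scale=0.3, size=(20, 2))
    X = pd.DataFrame(np.vstack([X0, X1]), columns=["u", "v"])
    y = np.array([0] * n + [1] * 20)
    return X, y


@pytest.fixture(scope="module")
def imbalanced():
    """Overlapping classes, 10:1 imbalance, one informative axis."""
    rng = np.random.default_rng(13)
    n0, n1 = 400, 40
    X0 = rng.normal(0.0, 1.0, size=(n0, 3))
    X1 = rng.normal(0.0, 1.0, size=(n1, 3))
    X1[:, 0] += 1.2
    X = pd.DataFrame(np.vstack([X0, X1]), columns=["a", "b", "c"])
    y = np.array([0] * n0 + [1] * n1)
    return X, y


class TestCostWeights:
    def test_weights_rescaled_to_sum_n(self):
        y = np.array([1, 1, 0, 0, 0])
        w = cost_weights(y, a.CostSpec(150, 3.5))
        assert w.sum() == pytest.approx(len(y))
        assert w[0] / w[2] == pytest.approx(150 / 3.5)

    def test_invalid_costs_rejected(self):
        with pytest.raises(ValueError):
            a.CostSpec(0, 1)
        with pytest.raises(ValueError):
            a.CostSpec(1, -2)

    def test_parse_ratio_string(self):
        c = a.CostSpec.parse("150:3.5")
        assert c.fn_cost == 150 and c.fp_cost == 3.5


class TestTraining:
    @pytest.mark.parametrize("learner", LEARNERS)
    def test_unit_costs_match_plain_learner(self, separable, learner):
        X, y = separable
        res = a.train(X, y, learner=learner, cost=a.CostSpec(1, 1), seed=0)
        plain = make_learner(learner, 0)
        plain.fit(X.to_numpy(), y)
        np.testing.assert_array_equal(res.predict(X), plain.predict(X.to_numpy()))

    @pytest.mark.parametrize("learner", ["decision_tree", "random_forest", "linear_svm"])
    def test_separable_fixture_perfect_resubstitution(self, separable, learner):
        X, y = separable
        res = a.train(X, y, learner=learner, seed=0)
        report = res.evaluate(X, y)
        assert report.g_mean == 1.0 and report.mcc == 1.0

    def test_extreme_fn_cost_predicts_everything_substrate(self, imbalanced):
        X, y = imbalanced
        res = a.train(X, y, learner="decision_tree", cost=a.CostSpec(1e6, 1), seed=0)
        report = res.evaluate(X, y)
        assert report.sensitivity == 1.0

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="both classes"):
            a.SubstrateClassifier(X, [1, 1, 1])

    def test_predict_missing_feature_named(self, separable):
        X, y = separable
        res = a.train(X, y, learner="decision_tree", seed=0)
        with pytest.raises(KeyError, match="v"):
            res.predict(X[["u"]])

    def test_empty_query_empty_predictions(self, separable):
        X, y = separable
        res = a.train(X, y, learner="decision_tree", seed=0)
        assert len(res.predict(X.iloc[:0])) == 0

    def test_restricts_to_selected_features(self, imbalanced):
        X, y = imbalanced
        res = a.train(X, y, features=["a"], learner="decision_tree", seed=0)
        scrambled = X.copy()
        rng = np.random.default_rng(0)
        scrambled["b"] = rng.normal(size=len(X))
        np.testing.assert_array_equal(res.predict(X), res.predict(scrambled))


class TestBagging:
    def test_identity_replicate_equals_base_learner(self, imbalanced):
        X, y = imbalanced
        bagged = a.train(
            X, y, learner="random_forest", cost=a.CostSpec(10, 1),
            bagging=a.BaggingConfig(n_estimators=1, bootstrap=False), seed=3,
        )
        single = a.train(X, y, learner="random_forest", cost=a.CostSpec(10, 1), seed=3)
        np.testing.assert_array_equal(bagged.predict(X), single.predict(X))

    def test_vote_tie_goes_to_substrate(self, separable):
        X, y = separable
        res = a.train(X, y, learner="decision_tree",
                      bagging=a.BaggingConfig(n_estimators=2), seed=0)
        votes = np.stack([est.predict(X.to_numpy()) for est in res.estimators])
        pred = res.predict(X)
        tie_rows = votes.sum(axis=0) == 1
        if tie_rows.any():
            assert (pred[tie_rows] == 1).all()

    def test_reproducible_given_seed(self, imbalanced):
        X, y = imbalanced
        r1 = a.train(X, y, bagging=a.BaggingConfig(5), cost=a.CostSpec(10, 1), seed=9)
        r2 = a.train(X, y, bagging=a.BaggingConfig(5), cost=a.CostSpec(10, 1), seed=9)
        np.testing.assert_array_equal(r1.predict(X), r2.predict(X))


class TestSerialization:
    @pytest.mark.parametrize("learner", ["naive_bayes", "random_forest"])
    def test_round_trip_identical_predictions(self, tmp_path, imbalanced, learner):
        X, y = imbalanced
        res = a.train(X, y, learner=learner, cost=a.CostSpec(65, 2.5), seed=1)
        p = res.save(tmp_path / "model.joblib")
        back = a.SubstrateClassifierResults.load(p)
        np.testing.assert_array_equal(res.predict(X), back.predict(X))

    def test_summary_mentions_configuration(self, imbalanced):
        X, y = imbalanced
        res = a.train(X, y, learner="random_forest", cost=a.CostSpec(65, 2.5), seed=1)
        text = res.summary()
        assert "random_forest" in text and "65:2.5" in text


class TestCrossValidation:
    def test_pooled_counts_conserve_class_totals(self, imbalanced):
        X, y = imbalanced
        report = a.cross_validate(X, y, learner="decision_tree", k=5, seed=0)
        cm = report.confusion
        assert cm.tp + cm.fn == int((y == 1).sum())
        assert cm.tn + cm.fp == int((y == 0).sum())

    def test_stratified_fold_sizes(self, imbalanced):
        X, y = imbalanced
        from sklearn.model_selection import StratifiedKFold

        sizes, subs = [], []
        for _, te in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
            sizes.append(len(te))
            subs.append(int(y[te].sum()))
        assert max(sizes) - min(sizes) <= 1
        assert max(subs) - min(subs) <= 1

    def test_perfect_learner_on_separable_data(self, separable):
        X, y = separable
        report = a.cross_validate(X, y, learner="linear_svm", k=5, seed=0)
        assert report.g_mean == 1.0 and report.accuracy == 1.0

    def test_k_exceeding_class_size_rejected(self, separable):
        X, y = separable
        with pytest.raises(ValueError, match="fewer than k"):
            a.cross_validate(X, y, k=30, seed=0)

    def test_ten_fold_supported(self, imbalanced):
        X, y = imbalanced
        report = a.cross_validate(X, y, learner="naive_bayes", k=10, seed=0)
        assert report.confusion.n == len(y)


class TestCostGrid:
    def test_single_candidate_returned(self, imbalanced):
        X, y = imbalanced
        best, table = a.cost_grid_search(
            X, y, learner="decision_tree", candidates=[a.CostSpec(5, 1)], k=5, seed=0
        )
        assert best == a.CostSpec(5, 1)
        assert len(table) == 1

    def test_heavy_fn_cost_wins_gmean_on_imbalanced_data(self, imbalanced):
        X, y = imbalanced
        best, table = a.cost_grid_search(
            X, y, learner="decision_tree",
            candidates=[a.CostSpec(1, 1), a.CostSpec(100, 1)], k=5, seed=0,
        )
        assert best == a.CostSpec(100, 1)
        assert len(table) == 2

    def test_empty_candidates_rejected(self, imbalanced):
        X, y = imbalanced
        with pytest.raises(ValueError):
            a.cost_grid_search(X, y, candidates=[])
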