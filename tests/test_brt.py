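"""Boosted regression trees: fitting, diagnostics, ensembles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import riverpart as rp
from riverpart.brt import _Booster, fit_tree
from riverpart.errors import InvalidArgumentError, SchemaError, UndefinedMetricError
from riverpart.sampling import TrainingSet

from conftest import make_signal_train


class TestFitTree:
    def test_constant_response_gives_single_leaf_newton_step(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        z = np.full(40, 0.3)
        w = np.full(40, 0.25)
        tree = fit_tree(X, z, w, tc=5)
        assert tree.n_leaves == 1
        assert tree.value[0] == pytest.approx(z.sum() / w.sum())

    def test_perfect_binary_split_recovers_group_newton_steps(self):
        n = 40
        X = np.zeros((n, 1))
        X[n // 2:, 0] = 1.0
        z = np.where(X[:, 0] == 0, -0.4, 0.4)
        w = np.full(n, 0.24)
        tree = fit_tree(X, z, w, tc=5, min_node=5)
        assert tree.n_splits == 1
        assert tree.threshold[0] == pytest.approx(0.5)
        left_val = -0.4 * (n // 2) / (0.24 * n // 2 + 0.24 * 0)  # sum z / sum w
        assert tree.value[tree.left[0]] == pytest.approx(-0.4 / 0.24)
        assert tree.value[tree.right[0]] == pytest.approx(0.4 / 0.24)

    @pytest.mark.parametrize("tc", [1, 2, 5, 8])
    def test_leaf_count_bounded_by_complexity(self, tc):
        rng = np.random.default_rng(tc)
        X = rng.normal(size=(200, 4))
        z = rng.normal(size=200)
        w = np.full(200, 0.25)
        tree = fit_tree(X, z, w, tc=tc, min_node=5)
        assert tree.n_leaves <= tc + 1
        # every row routes to exactly one leaf
        leaves = tree.predict(X)
        assert leaves.shape == (200,)


class TestFitBRT:
    def test_zero_trees_predicts_base_rate(self, signal_train):
        fit = rp.fit_brt(signal_train, n_trees=0, seed=0)
        p = fit.predict(signal_train.X).to_numpy()
        np.testing.assert_allclose(p, signal_train.response.mean(), atol=1e-12)

    def test_full_bag_training_deviance_nonincreasing(self, signal_train):
        schema = rp.FeatureSchema.for_columns(signal_train.X.columns)
        booster = _Booster(
            schema.transform(signal_train.X), signal_train.response.astype(float),
            tc=3, lr=0.05, bag_fraction=1.0, min_node=10,
            rng=np.random.default_rng(0),
        )
        devs = []
        for _ in range(8):
            booster.grow(20)
            devs.append(rp.bernoulli_deviance(signal_train.response, expit(booster.F)))
        assert all(b <= a + 1e-9 for a, b in zip(devs, devs[1:]))

    def test_separable_data_reaches_perfect_training_auc(self):
        train = make_signal_train(n_rows=300, noise=0.0, seed=3)
        fit = rp.fit_brt(train, tc=5, lr=0.2, n_trees=300, seed=1)
        p = fit.predict(train.X).to_numpy()
        assert rp.auc(train.response, p) > 0.999

    def test_single_class_rejected(self, signal_train):
        bad = TrainingSet.__new__(TrainingSet)  # bypass the balance check
        bad.reach_ids = signal_train.reach_ids
        bad.response = np.ones_like(signal_train.response)
        bad.X = signal_train.X
        with pytest.raises(InvalidArgumentError):
            rp.fit_brt(bad, n_trees=10, seed=0)

    def test_predictions_in_open_unit_interval(self, signal_fit, signal_train):
        p = signal_fit.predict(signal_train.X).to_numpy()
        assert (p > 0).all() and (p < 1).all()

    def test_missing_column_named_in_error(self, signal_fit, signal_train):
        with pytest.raises(SchemaError, match="sig_a"):
            rp.predict_rlo(signal_fit, signal_train.X.drop(columns=["sig_a"]))

    def test_hand_built_model_evaluation(self):
        # one tree: split on x0 at 0, leaves -1 (left) / +2 (right)
        tree = rp.RegressionTree(
            feature=np.array([0, -1, -1]),
            threshold=np.array([0.0, np.nan, np.nan]),
            left=np.array([1, -1, -1]),
            right=np.array([2, -1, -1]),
            value=np.array([0.0, -1.0, 2.0]),
            gains=np.zeros(2),
        )
        schema = rp.FeatureSchema(names=("x0", "x1"))
        model = rp.BRTFit(schema, intercept=0.5, trees=[tree, tree], lr=0.1,
                          tc=1, bag_fraction=1.0, min_node=1, seed=0)
        X = pd.DataFrame({"x0": [-1.0, 0.0, 3.0], "x1": [0.0, 0.0, 0.0]})
        expected = expit(0.5 + 0.1 * np.array([-2.0, -2.0, 4.0]))
        np.testing.assert_allclose(model.predict(X).to_numpy(), expected)

    def test_log_schema_applied_at_fit_and_predict(self):
        rng = np.random.default_rng(0)
        n = 400
        X = pd.DataFrame({"MeanFlow": np.exp(rng.normal(size=n)),
                          "other": rng.normal(size=n)})
        y = (X.MeanFlow > X.MeanFlow.median()).to_numpy(dtype=np.int64)
        train = TrainingSet(reach_ids=np.arange(n), response=y, X=X)
        fit = rp.fit_brt(train, tc=2, lr=0.2, n_trees=100, seed=0)
        assert "MeanFlow" in fit.schema.log_features
        # predictions respond monotonically to the flow signal
        lo = fit.predict(pd.DataFrame({"MeanFlow": [0.1], "other": [0.0]}))
        hi = fit.predict(pd.DataFrame({"MeanFlow": [10.0], "other": [0.0]}))
        assert hi.iloc[0] > lo.iloc[0]


class TestDevianceAndAUC:
    def test_perfect_predictions_near_zero_deviance(self):
        y = np.array([0, 1, 1, 0])
        assert rp.bernoulli_deviance(y, y.astype(float)) == pytest.approx(0.0, abs=1e-9)

    def test_uninformative_half_is_two_log_two(self):
        y = np.array([0, 1, 0, 1])
        assert rp.bernoulli_deviance(y, np.full(4, 0.5)) == pytest.approx(2 * np.log(2))

    def test_null_model_explains_nothing(self):
        y = np.array([0, 0, 1, 1, 1])
        assert rp.deviance_explained_pct(y, np.full(5, y.mean())) == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rp.bernoulli_deviance(np.array([0, 1]), np.array([0.5]))

    def test_auc_full_separation(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.4])
        assert rp.auc(y, s) == 1.0

    def test_auc_all_ties_is_half(self):
        y = np.array([1, 0, 1, 0])
        assert rp.auc(y, np.full(4, 0.3)) == pytest.approx(0.5)

    def test_auc_matches_pairwise_oracle_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = np.round(rng.random(200), 2)  # coarse scores force ties
        pos = s[y == 1]
        neg = s[y == 0]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        oracle = conc / (len(pos) * len(neg))
        assert rp.auc(y, s) == pytest.approx(oracle, abs=1e-12)
        assert rp.auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            rp.auc(np.ones(5), np.random.default_rng(0).random(5))


class TestRelativeInfluence:
    def test_sums_to_hundred(self, signal_fit):
        assert rp.relative_influence(signal_fit).sum() == pytest.approx(100.0, abs=1e-9)

    def test_unused_predictor_scores_zero(self):
        rng = np.random.default_rng(2)
        n = 200
        X = pd.DataFrame({"informative": rng.normal(size=n),
                          "constant": np.zeros(n)})
        y = (X.informative > X.informative.median()).to_numpy(dtype=np.int64)
        train = TrainingSet(reach_ids=np.arange(n), response=y, X=X)
        fit = rp.fit_brt(train, tc=2, lr=0.2, n_trees=50, seed=0)
        ri = rp.relative_influence(fit)
        assert ri["constant"] == 0.0

    def test_informative_predictor_dominates(self):
        rng = np.random.default_rng(3)
        n = 500
        cols = {f"noise_{k}": rng.normal(size=n) for k in range(9)}
        cols["signal"] = rng.normal(size=n)
        X = pd.DataFrame(cols)
        y = (X.signal > 0).to_numpy(dtype=np.int64)
        order = np.argsort(-y)
        n1 = y.sum()
        keep = np.concatenate([order[:n1], order[n1:2 * n1]])
        train = TrainingSet(reach_ids=keep, response=y[keep],
                            X=X.iloc[keep].reset_index(drop=True))
        fit = rp.fit_brt(train, tc=3, lr=0.2, n_trees=150, seed=1)
        assert rp.relative_influence(fit)["signal"] > 80.0

    def test_zero_split_model_warns(self, signal_train):
        fit = rp.fit_brt(signal_train, tc=1, lr=0.1, n_trees=0, seed=0)
        with pytest.warns(UserWarning, match="no splits"):
            ri = rp.relative_influence(fit)
        assert (ri == 0).all()


class TestPartialDependence:
    def test_intercept_only_model_is_flat(self, signal_train):
        fit = rp.fit_brt(signal_train, n_trees=0, seed=0)
        grid, vals = rp.partial_dependence(fit, "sig_a", grid_size=7)
        assert np.ptp(vals) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_averaging(self, signal_fit, signal_train):
        data = signal_train.X.iloc[:50]
        grid, vals = rp.partial_dependence(signal_fit, "sig_a", grid_size=9, data=data)
        for g, v in zip(grid, vals):
            mod = data.copy()
            mod["sig_a"] = g
            assert v == pytest.approx(signal_fit.predict(mod).mean(), abs=1e-12)

    def test_bivariate_matches_brute_force(self, signal_fit, signal_train):
        data = signal_train.X.iloc[:30]
        ga, gb, Z = rp.partial_dependence(
            signal_fit, ("sig_a", "sig_b"), grid_size=4, data=data, link=True
        )
        for i, a in enumerate(ga):
            for j, b in enumerate(gb):
                mod = data.copy()
                mod["sig_a"] = a
                mod["sig_b"] = b
                assert Z[i, j] == pytest.approx(
                    signal_fit.predict_link(mod).mean(), abs=1e-12
                )

    def test_unknown_variable_rejected(self, signal_fit):
        with pytest.raises(SchemaError):
            rp.partial_dependence(signal_fit, "nope")


class TestInteractionStrength:
    @staticmethod
    def _train(kind, seed=0, n=800):
        # probabilistic labels so the additive case really is additive on
        # the logit scale (a deterministic threshold would be a ridge)
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n),
                          "c": rng.normal(size=n)})
        score = X.a + X.b if kind == "additive" else 1.5 * X.a * X.b
        y = (rng.random(n) < expit(score)).astype(np.int64)
        m = min(y.sum(), n - y.sum())
        i1 = np.flatnonzero(y == 1)[:m]
        i0 = np.flatnonzero(y == 0)[:m]
        keep = np.concatenate([i1, i0])
        return TrainingSet(reach_ids=keep, response=y[keep],
                           X=X.iloc[keep].reset_index(drop=True))

    def test_additive_model_scores_exactly_zero(self):
        # single-split trees make the fitted function additive by
        # construction, which is the statistic's zero-interaction anchor
        stumps = rp.fit_brt(self._train("additive"), tc=1, lr=0.1, n_trees=200, seed=1)
        assert rp.interaction_strength(stumps, ("a", "b"), grid_size=10) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_multiplicative_truth_scores_higher_than_additive(self):
        add = rp.fit_brt(self._train("additive"), tc=3, lr=0.1, n_trees=200, seed=1)
        mult = rp.fit_brt(self._train("multiplicative"), tc=3, lr=0.1, n_trees=200, seed=1)
        s_add = rp.interaction_strength(add, ("a", "b"), grid_size=10)
        s_mult = rp.interaction_strength(mult, ("a", "b"), grid_size=10)
        assert s_mult > 4 * s_add

    def test_symmetry(self, signal_fit):
        ab = rp.interaction_strength(signal_fit, ("sig_a", "sig_b"), grid_size=8)
        ba = rp.interaction_strength(signal_fit, ("sig_b", "sig_a"), grid_size=8)
        assert ab == ba

    def test_constant_predictor_scores_zero_with_warning(self, signal_fit, signal_train):
        data = signal_train.X.copy()
        data["sig_b"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            s = rp.interaction_strength(signal_fit, ("sig_a", "sig_b"), data=data)
        assert s == 0.0


class TestCrossValidation:
    def test_folds_partition_rows(self, signal_train):
        from riverpart.brt import _stratified_folds

        y = signal_train.response.astype(float)
        assignment = _stratified_folds(y, 10, np.random.default_rng(0))
        assert len(assignment) == len(y)
        assert set(assignment) == set(range(10))
        for f in range(10):
            assert set(y[assignment == f]) == {0.0, 1.0}

    def test_optimum_on_step_grid(self, signal_train):
        trace = rp.cv_optimal_ntrees(signal_train, tc=2, lr=0.1, folds=4,
                                     step=25, max_trees=200, seed=0)
        assert trace.optimal_ntrees % 25 == 0
        assert trace.mean_deviance.min() == trace.mean_deviance[
            list(trace.grid).index(trace.optimal_ntrees)
        ]

    def test_null_data_prefers_few_trees(self):
        small_wins, large_wins = 0, 0
        for seed in range(4):
            rng = np.random.default_rng(seed)
            n = 120
            X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
            y = np.repeat([0, 1], n // 2)
            train = TrainingSet(reach_ids=np.arange(n), response=y, X=X)
            trace = rp.cv_optimal_ntrees(train, tc=2, lr=0.1, folds=4, step=25,
                                         max_trees=150, patience=10, seed=seed)
            if trace.optimal_ntrees == trace.grid[0]:
                small_wins += 1
            elif trace.optimal_ntrees == trace.grid[-1]:
                large_wins += 1
        assert small_wins > large_wins

    def test_too_few_rows_per_class_rejected(self):
        n = 12
        X = pd.DataFrame({"a": np.arange(n, dtype=float)})
        y = np.repeat([0, 1], n // 2)
        train = TrainingSet(reach_ids=np.arange(n), response=y, X=X)
        with pytest.raises(InvalidArgumentError, match="stratification"):
            rp.cv_optimal_ntrees(train, folds=10, seed=0)


@pytest.fixture(scope="module")
def ensemble(signal_train):
    return rp.fit_ensemble(signal_train, n_sims=5, holdout=0.2, tc=3,
                           lr=0.1, n_trees=120, seed=21)


class TestEnsemble:
    def test_withheld_sizes(self, ensemble, signal_train):
        import math

        expected = math.ceil(0.2 * len(signal_train))
        for m in ensemble.members:
            assert len(m.withheld_ids) == expected

    def test_determinism_under_master_seed(self, ensemble, signal_train):
        again = rp.fit_ensemble(signal_train, n_sims=5, holdout=0.2, tc=3,
                                lr=0.1, n_trees=120, seed=21)
        assert [m.auc for m in again.members] == [m.auc for m in ensemble.members]
        assert [m.deviance_explained_pct for m in again.members] == [
            m.deviance_explained_pct for m in ensemble.members
        ]

    def test_strong_signal_gives_high_withheld_auc(self, ensemble):
        assert np.mean([m.auc for m in ensemble.members]) > 0.9

    def test_serialisation_round_trip_exact(self, ensemble, signal_train, tmp_path):
        path = tmp_path / "ensemble.json"
        ensemble.save(path)
        again = rp.BRTEnsemble.load(path)
        a = ensemble.predict_matrix(signal_train.X).to_numpy()
        b = again.predict_matrix(signal_train.X).to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_excessive_holdout_rejected(self, signal_train):
        with pytest.raises(InvalidArgumentError):
            rp.fit_ensemble(signal_train, n_sims=2, holdout=0.999, n_trees=10, seed=0)

    def test_reselection_lets_members_choose_their_own_size(self):
        train = make_signal_train(n_rows=200, seed=8)
        ens = rp.fit_ensemble(train, n_sims=2, n_trees=50, tc=2, lr=0.1, seed=1,
                              reselect_trees=True, reselect_folds=3,
                              reselect_step=25)
        for m in ens.members:
            assert m.model.n_trees % 25 == 0
            assert 25 <= m.model.n_trees <= 100
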