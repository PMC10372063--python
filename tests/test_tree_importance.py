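"""CART regression tree: splits, importance, evaluation, determinism."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dedair import tree_importance as ti


def brute_force_tree(X: np.ndarray, y: np.ndarray, max_depth: int, min_leaf: int):
    """Independent exhaustive-search recursion: returns per-row predictions
    and the total weighted impurity decrease accumulated per feature."""
    n_total = len(y)
    importances = np.zeros(X.shape[1])
    pred = np.empty(len(y))

    def var(v):
        return float(np.var(v)) if v.size else 0.0

    def rec(idx, depth):
        yi = y[idx]
        if depth >= max_depth or var(yi) <= 0 or idx.size < 2 * min_leaf:
            pred[idx] = yi.mean()
            return
        best = None
        for j in range(X.shape[1]):
            xs = np.unique(X[idx, j])
            for a, b in zip(xs[:-1], xs[1:]):
                thr = (a + b) / 2
                left = idx[X[idx, j] <= thr]
                right = idx[X[idx, j] > thr]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                gain = var(yi) - (len(left) * var(y[left]) + len(right) * var(y[right])) / idx.size
                if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                    best = (gain, j, thr, left, right)
        if best is None:
            pred[idx] = yi.mean()
            return
        gain, j, thr, left, right = best
        importances[j] += (idx.size / n_total) * gain
        rec(left, depth + 1)
        rec(right, depth + 1)

    rec(np.arange(len(y)), 0)
    return pred, importances


def _frame(X: np.ndarray, y: np.ndarray, factors) -> pd.DataFrame:
    frame = pd.DataFrame(X, columns=list(factors))
    frame["DED"] = y
    return frame


class TestTemporalSplit:
    def test_seventy_thirty_counting(self):
        table = pd.DataFrame({"v": range(10)})
        train, test = ti.temporal_split(table, 0.7)
        assert list(train["v"]) == list(range(7))
        assert list(test["v"]) == [7, 8, 9]

    def test_empty_test_side_is_an_error(self):
        with pytest.raises(ValueError):
            ti.temporal_split(pd.DataFrame({"v": range(10)}), 0.999)

    def test_sixty_months_hold_out_latest_eighteen(self):
        idx = pd.MultiIndex.from_product([range(2016, 2021), range(1, 13)],
                                         names=["year", "month"])
        table = pd.DataFrame({"v": range(60)}, index=idx)
        train, test = ti.temporal_split(table, 0.7)
        assert len(test) == 18
        assert test.index[0] == (2019, 7)  # July 2019 onward held out


class TestFit:
    def test_separable_step_function(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 20)
        y = np.where(x < 5, 0.0, 10.0)
        model = ti.fit_regression_tree(
            _frame(x[:, None], y, ["PM10"]), ["PM10"], "DED",
            ti.Hyperparameters(max_depth=1, min_samples_leaf=1),
        )
        root = model.root
        assert root.feature == "PM10"
        assert max(x[x < 5]) < root.threshold <= min(x[x >= 5])
        assert {root.left.value, root.right.value} == {0.0, 10.0}

    def test_constant_response_single_leaf(self):
        table = _frame(np.arange(12, dtype=float)[:, None], np.full(12, 3.3), ["AT"])
        model = ti.fit_regression_tree(table, ["AT"], "DED")
        assert model.root.is_leaf and model.root.value == pytest.approx(3.3)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_recursion(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (12, 2))
        y = rng.uniform(0, 10, 12)
        table = _frame(X, y, ["a", "b"])
        hp = ti.Hyperparameters(max_depth=3, min_samples_leaf=2)
        model = ti.fit_regression_tree(table, ["a", "b"], "DED", hp)
        pred_oracle, imp_oracle = brute_force_tree(X, y, 3, 2)
        assert np.allclose(model.predict(table), pred_oracle, atol=1e-12)
        imp = ti.feature_importance(model).importance
        total = imp_oracle.sum()
        assert np.allclose(imp.to_numpy(), imp_oracle / total, atol=1e-12)

    def test_matches_sklearn_cross_check(self):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (60, 3))
        y = 3 * X[:, 0] + rng.normal(0, 0.2, 60)
        table = _frame(X, y, ["a", "b", "c"])
        hp = ti.Hyperparameters(max_depth=4, min_samples_leaf=3)
        mine = ti.fit_regression_tree(table, ["a", "b", "c"], "DED", hp)
        ref = sklearn_tree.DecisionTreeRegressor(
            max_depth=4, min_samples_leaf=3, random_state=0
        ).fit(X, y)
        assert np.allclose(mine.predict(table), ref.predict(X), atol=1e-10)
        imp = ti.feature_importance(mine).importance
        assert np.allclose(imp.to_numpy(), ref.feature_importances_, atol=1e-10)

    def test_determinism_and_training_mse_monotone_in_depth(self):
        rng = np.random.default_rng(17)
        X = rng.uniform(0, 1, (60, 3))
        y = np.sin(6 * X[:, 0]) + 0.5 * X[:, 1] + rng.normal(0, 0.1, 60)
        table = _frame(X, y, ["a", "b", "c"])
        prev_mse = np.inf
        for depth in range(1, 6):
            hp = ti.Hyperparameters(max_depth=depth, min_samples_leaf=2)
            m1 = ti.fit_regression_tree(table, ["a", "b", "c"], "DED", hp)
            m2 = ti.fit_regression_tree(table, ["a", "b", "c"], "DED", hp)
            assert m1.to_dict() == m2.to_dict()
            mse = float(np.mean((m1.predict(table) - y) ** 2))
            assert mse <= prev_mse + 1e-12
            prev_mse = mse


class TestImportance:
    def test_single_informative_factor_takes_all(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.repeat([0.0, 1.0], 10), rng.uniform(0, 1, 20) * 0])
        y = np.repeat([0.0, 5.0], 10)
        table = _frame(X, y, ["x1", "x2"])
        model = ti.fit_regression_tree(table, ["x1", "x2"], "DED",
                                       ti.Hyperparameters(max_depth=2, min_samples_leaf=2))
        imp = ti.feature_importance(model)
        assert imp.importance["x1"] == pytest.approx(1.0)
        assert imp.importance["x2"] == 0.0

    def test_importance_sums_to_one_with_any_split(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (40, 3))
        y = X[:, 1] + rng.normal(0, 0.05, 40)
        model = ti.fit_regression_tree(_frame(X, y, ["a", "b", "c"]), ["a", "b", "c"], "DED")
        imp = ti.feature_importance(model)
        assert not imp.no_splits
        assert imp.importance.sum() == pytest.approx(1.0)

    def test_single_leaf_flagged_no_splits(self):
        table = _frame(np.arange(10, dtype=float)[:, None], np.zeros(10), ["a"])
        model = ti.fit_regression_tree(table, ["a"], "DED")
        imp = ti.feature_importance(model)
        assert imp.no_splits and (imp.importance == 0).all()

    def test_planted_dominant_factor_ranks_first(self):
        """PM10 drives the response, AT and WS are pure noise: PM10 must lead
        the importance ranking in >= 95% of seeds."""
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            pm10 = rng.uniform(30, 110, 60)
            table = pd.DataFrame({
                "PM10": pm10, "AT": rng.normal(7, 13, 60), "WS": rng.normal(2.7, 0.4, 60),
            })
            table["DED"] = 5 + 0.06 * pm10 + rng.normal(0, 0.8, 60)
            model = ti.fit_regression_tree(table, ["PM10", "AT", "WS"], "DED")
            imp = ti.feature_importance(model).importance
            wins += imp.idxmax() == "PM10"
        assert wins / n_seeds >= 0.95

    def test_permutation_importance_prefers_signal(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 1, (60, 2))
        y = 4 * X[:, 0] + rng.normal(0, 0.1, 60)
        table = _frame(X, y, ["sig", "noise"])
        model = ti.fit_regression_tree(table, ["sig", "noise"], "DED")
        perm = ti.permutation_importance(model, table, seed=1)
        assert perm["sig"] > perm["noise"]


class TestEvaluate:
    def test_perfect_predictions_zero_error(self):
        table = _frame(np.repeat([0.0, 1.0], 5)[:, None], np.repeat([2.0, 8.0], 5), ["a"])
        model = ti.fit_regression_tree(table, ["a"], "DED",
                                       ti.Hyperparameters(max_depth=1, min_samples_leaf=1))
        metrics = ti.evaluate(model, table)
        assert metrics.mse == metrics.rmse == metrics.mae == 0.0

    def test_hand_arithmetic_metrics(self):
        table = _frame(np.zeros((4, 1)), np.full(4, 3.0), ["a"])
        model = ti.fit_regression_tree(
            table, ["a"], "DED", ti.Hyperparameters(min_samples_leaf=2)
        )  # single leaf predicting 3.0
        test = _frame(np.zeros((2, 1)), np.array([4.0, 2.0]), ["a"])
        metrics = ti.evaluate(model, test)
        assert metrics.mae == pytest.approx(1.0)
        assert metrics.mse == pytest.approx(1.0)
        assert metrics.rmse == pytest.approx(1.0)

    def test_toy_tree_metrics_match_hand_sums(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (20, 2))
        y = rng.uniform(0, 5, 20)
        table = _frame(X, y, ["a", "b"])
        model = ti.fit_regression_tree(table, ["a", "b"], "DED")
        test = _frame(rng.uniform(0, 1, (5, 2)), rng.uniform(0, 5, 5), ["a", "b"])
        metrics = ti.evaluate(model, test)
        pred = model.predict(test)
        resid = pred - test["DED"].to_numpy()
        assert metrics.mse == pytest.approx(np.mean(resid ** 2))
        assert metrics.rmse == pytest.approx(np.sqrt(np.mean(resid ** 2)))
        assert metrics.mae == pytest.approx(np.mean(np.abs(resid)))
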