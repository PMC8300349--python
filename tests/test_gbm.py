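"""Boosting engine: CART oracle equivalence, loss monotonicity, search."""

import numpy as np
import pytest

from spectracv.gbm import (
    GBMConfig,
    GBMRegressor,
    SearchSpec,
    fit_tree,
    random_search,
    tree_predict,
)


def brute_stump_sse(X, y, min_leaf=1):
    """Exhaustive depth-1 search over (feature, midpoint threshold)."""
    best = np.sum((y - y.mean()) ** 2)
    for j in range(X.shape[1]):
        u = np.unique(X[:, j])
        for t in (u[:-1] + u[1:]) / 2:
            L = X[:, j] <= t
            if L.sum() < min_leaf or (~L).sum() < min_leaf:
                continue
            sse = np.sum((y[L] - y[L].mean()) ** 2) + np.sum(
                (y[~L] - y[~L].mean()) ** 2
            )
            best = min(best, sse)
    return best


class TestFitTree:
    def test_constant_residuals_give_single_leaf(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        tree = fit_tree(X, np.full(10, 3.25), max_depth=3)
        assert tree.n_leaves == 1
        np.testing.assert_allclose(tree_predict(tree, X), 3.25)

    def test_step_function_stump(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        r = np.array([0.0, 0.0, 1.0, 1.0])
        tree = fit_tree(X, r, max_depth=1)
        assert tree.feature[0] == 0
        assert tree.threshold[0] == 0.0  # midpoint of -1 and 1
        np.testing.assert_allclose(sorted(set(tree_predict(tree, X))), [0.0, 1.0])

    def test_depth1_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            X = rng.standard_normal((50, 8))
            y = rng.standard_normal(50)
            tree = fit_tree(X, y, max_depth=1)
            sse = np.sum((y - tree_predict(tree, X)) ** 2)
            np.testing.assert_allclose(sse, brute_stump_sse(X, y), atol=1e-9)

    def test_depth1_matches_sklearn_cart(self, rng):
        from sklearn.tree import DecisionTreeRegressor

        for _ in range(20):
            X = rng.standard_normal((40, 5))
            y = rng.standard_normal(40)
            tree = fit_tree(X, y, max_depth=1)
            sk = DecisionTreeRegressor(max_depth=1).fit(X, y)
            np.testing.assert_allclose(
                np.sum((y - tree_predict(tree, X)) ** 2),
                np.sum((y - sk.predict(X)) ** 2),
                atol=1e-8,
            )

    def test_min_samples_leaf_respected(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        tree = fit_tree(X, y, max_depth=4, min_samples_leaf=7)
        # count rows reaching each leaf
        pred = tree_predict(tree, X)
        for leaf_val in set(pred):
            assert np.sum(pred == leaf_val) >= 7

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            fit_tree(np.empty((0, 3)), np.empty(0))


class TestGBM:
    def test_constant_target(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        est = GBMRegressor(n_trees=5, min_samples_leaf=1).fit(X, np.full(20, 7.0))
        np.testing.assert_allclose(est.predict(X), 7.0)
        assert all(t.n_leaves == 1 for t in est.trees_)

    def test_single_stump_closed_form(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([1.0, 3.0, 7.0, 9.0])
        est = GBMRegressor(
            n_trees=1, learning_rate=1.0, max_depth=1, min_samples_leaf=1
        ).fit(X, y)
        np.testing.assert_allclose(est.predict(X), [2.0, 2.0, 8.0, 8.0])
        # training RMSE equals the pooled within-group SD
        np.testing.assert_allclose(est.training_loss_curve_[-1], 1.0)

    def test_training_loss_non_increasing(self, rng):
        for _ in range(10):
            X = rng.standard_normal((60, 6))
            y = X[:, 0] - 2 * X[:, 3] + 0.3 * rng.standard_normal(60)
            est = GBMRegressor(
                n_trees=80, learning_rate=0.2, max_depth=2, min_samples_leaf=2
            ).fit(X, y)
            lc = np.asarray(est.training_loss_curve_)
            assert np.all(np.diff(lc) <= 1e-12)

    def test_later_model_not_worse_than_early(self, rng):
        X = rng.standard_normal((80, 5))
        y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(80)
        curves = GBMRegressor(n_trees=200, max_depth=2).fit(X, y).training_loss_curve_
        assert curves[199] <= curves[19]

    def test_zero_tree_model_predicts_f0(self):
        est = GBMRegressor.from_dict(
            {
                "params": GBMRegressor().get_params(),
                "f0": 4.5,
                "n_features_in": 3,
                "trees": [],
                "training_loss_curve": [],
            }
        )
        np.testing.assert_allclose(est.predict(np.zeros((5, 3))), 4.5)

    def test_row_permutation_invariance(self, rng):
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        est = GBMRegressor(n_trees=20).fit(X, y)
        perm = rng.permutation(50)
        np.testing.assert_allclose(est.predict(X[perm])[np.argsort(perm)], est.predict(X))

    def test_column_mismatch_errors(self, rng):
        est = GBMRegressor(n_trees=2, min_samples_leaf=1).fit(
            rng.standard_normal((20, 4)), rng.standard_normal(20)
        )
        with pytest.raises(ValueError, match="columns"):
            est.predict(rng.standard_normal((5, 3)))

    def test_non_finite_input_errors(self):
        X = np.ones((10, 2))
        y = np.ones(10)
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            GBMRegressor(min_samples_leaf=1).fit(X, y)

    def test_componentwise_stump_base_learner_uses_depth_one(self, rng):
        X = rng.standard_normal((60, 5))
        y = X[:, 1] + 0.1 * rng.standard_normal(60)
        est = GBMRegressor(
            n_trees=30, max_depth=6, base_learner="componentwise_stump"
        ).fit(X, y)
        assert all(t.depth <= 1 for t in est.trees_)
        # each base learner splits on exactly one wavenumber
        assert all(len([f for f in t.feature if f >= 0]) <= 1 for t in est.trees_)

    def test_json_round_trip(self, rng, tmp_path):
        X = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        est = GBMRegressor(n_trees=10, min_samples_leaf=2).fit(X, y)
        est.save_json(tmp_path / "model.json")
        back = GBMRegressor.load_json(tmp_path / "model.json")
        np.testing.assert_allclose(back.predict(X), est.predict(X))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GBMConfig(n_trees=0)
        with pytest.raises(ValueError):
            GBMConfig(learning_rate=1.5)


class TestRandomSearch:
    def _data(self, rng, n=80):
        X = rng.standard_normal((n, 4))
        return X, X[:, 0] + 0.2 * rng.standard_normal(n)

    def test_budget_one_returns_single_draw(self, rng):
        X, y = self._data(rng)
        spec = SearchSpec(
            n_trees_grid=(20,), lr_grid=(0.1,), depth_grid=(2,), leaf_grid=(1,),
            budget=1, seed=0,
        )
        best, table = random_search(X, y, spec)
        assert len(table) == 1
        assert best == GBMConfig(20, 0.1, 2, 1, seed=0)

    def test_draws_lie_on_published_grids(self, rng):
        X, y = self._data(rng)
        spec = SearchSpec(n_trees_grid=tuple(range(10, 201, 10)), budget=6, seed=3)
        _, table = random_search(X, y, spec)
        for _, row in table.iterrows():
            assert row.n_trees % 10 == 0 and 10 <= row.n_trees <= 8000
            assert row.min_samples_leaf in set(range(1, 101, 5))
            assert 1 <= row.max_depth <= 80
            assert 0.001 <= row.learning_rate <= 1.0

    def test_selected_config_beats_median(self, rng):
        wins = 0
        for s in range(5):
            X, y = self._data(rng, n=100)
            spec = SearchSpec(
                n_trees_grid=(10, 50, 100),
                lr_grid=(0.01, 0.1, 0.5),
                depth_grid=(1, 2, 3),
                leaf_grid=(1, 6),
                budget=8,
                seed=s,
            )
            best, table = random_search(X, y, spec)
            row = table[
                (table.n_trees == best.n_trees)
                & (table.learning_rate == best.learning_rate)
                & (table.max_depth == best.max_depth)
                & (table.min_samples_leaf == best.min_samples_leaf)
            ]
            if row["mean_rmse"].iloc[0] <= table["mean_rmse"].median():
                wins += 1
        assert wins == 5

    def test_outer_data_unused(self, rng):
        """The search only ever sees the rows it is given."""
        X, y = self._data(rng)
        spec = SearchSpec(
            n_trees_grid=(20,), lr_grid=(0.1,), depth_grid=(2,), leaf_grid=(1,),
            budget=2, seed=1,
        )
        best_a, _ = random_search(X[:60], y[:60], spec)
        X2 = X.copy()
        X2[60:] = 1e6  # corrupt rows outside the training slice
        best_b, _ = random_search(X2[:60], y[:60], spec)
        assert best_a == best_b
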