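"""Least-squares gradient boosting of depth-limited regression trees.

The model is the stagewise additive expansion

    F_M(x) = f0 + lr * sum_{m=1..M} tree_m(x),

where ``f0`` is the training mean, each tree is fit by greedy binary CART
on squared error to the current residuals, and ``lr`` (shrinkage) damps
every stage.  Split search uses per-feature histograms: when a feature has
at most ``max_bins`` distinct training values the candidate thresholds are
exactly the midpoints between consecutive sorted unique values (so small
problems are searched exhaustively); otherwise up to ``max_bins`` quantile
bins are used.  Ties break to the lowest wavenumber index, then the lowest
threshold.

``random_search`` draws hyperparameter configurations uniformly from the
published grids (number of trees 10–8000 by 10, learning rate 0.001–1 by
0.001, depth 1–80, minimum leaf 1–100 by 5) and scores each by inner
k-fold CV on the training data only, selecting the configuration with the
lowest mean held-out RMSE (ties: higher r², then first drawn).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import _hist

__all__ = [
    "GBMConfig",
    "SearchSpec",
    "GBMRegressor",
    "fit_tree",
    "fit_gbm",
    "predict_gbm",
    "random_search",
]


@dataclass(frozen=True)
class GBMConfig:
    """Hyperparameters of one boosting model."""

    n_trees: int = 100
    learning_rate: float = 0.1
    max_depth: int = 3
    min_samples_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in (0, 1]")
        if self.max_depth < 1 or self.min_samples_leaf < 1:
            raise ValueError("max_depth and min_samples_leaf must be >= 1")

    def estimator(self, **overrides) -> "GBMRegressor":
        return GBMRegressor(
            n_trees=self.n_trees,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.seed,
            **overrides,
        )


@dataclass(frozen=True)
class SearchSpec:
    """Random-search controls; defaults follow the published grids."""

    n_trees_grid: Tuple[int, ...] = tuple(range(10, 8001, 10))
    lr_grid: Tuple[float, ...] = tuple(np.round(np.arange(1, 1001) * 0.001, 3))
    depth_grid: Tuple[int, ...] = tuple(range(1, 81))
    leaf_grid: Tuple[int, ...] = tuple(range(1, 101, 5))
    budget: int = 50
    inner_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(len(self.n_trees_grid), len(self.lr_grid), len(self.depth_grid), len(self.leaf_grid)) == 0:
            raise ValueError("all grids must be non-empty")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.inner_k < 2:
            raise ValueError("inner_k must be >= 2")


class _Tree:
    """Flat array representation of one fitted regression tree."""

    __slots__ = ("feature", "threshold", "left", "right", "value", "depth")

    def __init__(self):
        self.feature: List[int] = []
        self.threshold: List[float] = []
        self.left: List[int] = []
        self.right: List[int] = []
        self.value: List[float] = []
        self.depth = 0

    def add_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(0.0)
        return len(self.feature) - 1

    def arrays(self):
        return (
            np.asarray(self.feature, dtype=np.int64),
            np.asarray(self.threshold, dtype=np.float64),
            np.asarray(self.left, dtype=np.int64),
            np.asarray(self.right, dtype=np.int64),
            np.asarray(self.value, dtype=np.float64),
        )

    @property
    def n_leaves(self) -> int:
        return sum(1 for f in self.feature if f < 0)

    def to_dict(self) -> dict:
        return {
            "feature": list(self.feature),
            "threshold": list(self.threshold),
            "left": list(self.left),
            "right": list(self.right),
            "value": list(self.value),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Tree":
        t = cls()
        t.feature = [int(v) for v in d["feature"]]
        t.threshold = [float(v) for v in d["threshold"]]
        t.left = [int(v) for v in d["left"]]
        t.right = [int(v) for v in d["right"]]
        t.value = [float(v) for v in d["value"]]
        return t


def _bin_features(X: np.ndarray, max_bins: Optional[int]):
    """Per-feature bin codes and split-edge values.

    Edges are midpoints between consecutive unique values when the feature
    has at most ``max_bins`` distinct values (exhaustive search), otherwise
    deduplicated quantile cuts.  Code c means the value lies at or below
    edge c (and above edge c-1).
    """
    n, p = X.shape
    codes = np.empty((p, n), dtype=np.uint16)
    edges: List[np.ndarray] = []
    quant = None
    if max_bins is not None and n > max_bins:
        quant = np.quantile(X, np.arange(1, max_bins) / max_bins, axis=0)
    for j in range(p):
        x = X[:, j]
        if quant is None:
            uniq = np.unique(x)
            if max_bins is None or len(uniq) <= max_bins:
                e = (uniq[:-1] + uniq[1:]) / 2.0
            else:
                e = np.unique(np.quantile(x, np.arange(1, max_bins) / max_bins))
        else:
            e = np.unique(quant[:, j])
        if len(e) >= np.iinfo(np.uint16).max:
            raise ValueError("too many candidate thresholds for uint16 codes")
        codes[j, :] = np.searchsorted(e, x, side="left")
        edges.append(e)
    return codes, edges


class GBMRegressor(BaseEstimator, RegressorMixin):
    """Gradient boosting regressor (squared-error loss, shrinkage).

    Parameters
    ----------
    n_trees, learning_rate, max_depth, min_samples_leaf : the four tuned
        hyperparameters.
    max_bins : candidate-threshold budget per feature; ``None`` forces the
        exact exhaustive midpoint search.
    base_learner : ``"tree"`` (default, one wavenumber per split) or
        ``"componentwise_stump"`` (one wavenumber per boosting stage, i.e.
        depth-1 base learners).
    random_state : kept for API symmetry; fitting is deterministic.

    Attributes
    ----------
    f0_ : initial constant prediction (training mean).
    trees_ : fitted trees in boosting order.
    training_loss_curve_ : training RMSE after each stage.
    """

    def __init__(
        self,
        n_trees: int = 100,
        learning_rate: float = 0.1,
        max_depth: int = 3,
        min_samples_leaf: int = 5,
        max_bins: Optional[int] = 256,
        base_learner: str = "tree",
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_bins = max_bins
        self.base_learner = base_learner
        self.random_state = random_state

    # -- internal ------------------------------------------------------

    def _effective_depth(self) -> int:
        if self.base_learner == "componentwise_stump":
            return 1
        if self.base_learner != "tree":
            raise ValueError("base_learner must be 'tree' or 'componentwise_stump'")
        return self.max_depth

    def fit(self, X, y):
        GBMConfig(self.n_trees, self.learning_rate, self.max_depth, self.min_samples_leaf)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one row per y value")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in X or y")
        if len(y) < 2 * self.min_samples_leaf:
            raise ValueError("need at least 2 * min_samples_leaf training rows")

        codes, edges = _bin_features(X, self.max_bins)
        self.n_features_in_ = X.shape[1]
        self.f0_ = float(y.mean())
        depth_cap = self._effective_depth()

        F = np.full(len(y), self.f0_)
        self.trees_ = []
        self.training_loss_curve_ = []
        tol = 1e-12 * max(1.0, float(np.sum((y - self.f0_) ** 2)))
        n_bins_max = max(len(e) + 1 for e in edges)
        n_edges = np.asarray([len(e) for e in edges], dtype=np.int64)
        all_rows = np.arange(len(y), dtype=np.int64)

        for _ in range(self.n_trees):
            resid = y - F
            tree, train_pred = _grow_tree(
                codes,
                edges,
                n_edges,
                n_bins_max,
                resid,
                all_rows,
                depth_cap,
                self.min_samples_leaf,
                tol,
            )
            self.trees_.append(tree)
            F = F + self.learning_rate * train_pred
            self.training_loss_curve_.append(float(np.sqrt(np.mean((y - F) ** 2))))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[-1] if X.ndim == 2 else '?'} columns, "
                f"model was fit on {self.n_features_in_}"
            )
        out = np.zeros(X.shape[0])
        for tree in self.trees_:
            _hist.predict_tree(X, *tree.arrays(), out)
        return self.f0_ + self.learning_rate * out

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "f0": self.f0_,
            "n_features_in": self.n_features_in_,
            "trees": [t.to_dict() for t in self.trees_],
            "training_loss_curve": list(self.training_loss_curve_),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "GBMRegressor":
        est = cls(**d["params"])
        est.f0_ = float(d["f0"])
        est.n_features_in_ = int(d["n_features_in"])
        est.trees_ = [_Tree.from_dict(t) for t in d["trees"]]
        est.training_loss_curve_ = [float(v) for v in d["training_loss_curve"]]
        return est

    @classmethod
    def load_json(cls, path) -> "GBMRegressor":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _grow_tree(codes, edges, n_edges, n_bins_max, resid, all_rows, max_depth, min_leaf, tol):
    """Greedy level-by-level CART on squared error; returns the tree and the
    fitted values on the training rows."""
    tree = _Tree()
    train_pred = np.empty(len(resid))
    root = tree.add_node()
    stack = [(root, all_rows, 0, None)]  # node, rows, depth, histogram
    while stack:
        node, rows, depth, hist = stack.pop()
        n_tot = rows.size
        s_tot = float(resid[rows].sum())
        make_leaf = depth >= max_depth or n_tot < 2 * min_leaf
        feat = -1
        if not make_leaf:
            if hist is None:
                hist = _hist.build_hist(codes, rows, resid, n_bins_max)
            feat, edge, _ = _hist.best_split(
                hist[0], hist[1], n_edges, min_leaf, n_tot, s_tot, tol
            )
            make_leaf = feat < 0
        if make_leaf:
            tree.value[node] = s_tot / n_tot
            train_pred[rows] = tree.value[node]
            tree.depth = max(tree.depth, depth)
            continue
        thr = edges[feat][edge]
        go_left = codes[feat, rows] <= edge
        left_rows = rows[go_left]
        right_rows = rows[~go_left]
        tree.feature[node] = int(feat)
        tree.threshold[node] = float(thr)
        lid = tree.add_node()
        rid = tree.add_node()
        tree.left[node] = lid
        tree.right[node] = rid
        # histogram subtraction: build the smaller child, derive the sibling
        if depth + 1 >= max_depth:
            lh = rh = None
        elif left_rows.size <= right_rows.size:
            lh = _hist.build_hist(codes, left_rows, resid, n_bins_max)
            rh = _hist.sub_hist(hist[0], hist[1], lh[0], lh[1])
        else:
            rh = _hist.build_hist(codes, right_rows, resid, n_bins_max)
            lh = _hist.sub_hist(hist[0], hist[1], rh[0], rh[1])
        stack.append((lid, left_rows, depth + 1, lh))
        stack.append((rid, right_rows, depth + 1, rh))
    return tree, train_pred


# --------------------------------------------------------------------------
# Spec-level operation wrappers
# --------------------------------------------------------------------------


def fit_tree(
    X,
    residuals,
    max_depth: int = 3,
    min_samples_leaf: int = 1,
    seed: int = 0,
    max_bins: Optional[int] = None,
):
    """Fit a single CART regression tree to residuals (exact search by default)."""
    X = np.asarray(X, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    if X.size == 0 or residuals.size == 0:
        raise ValueError("empty input")
    codes, edges = _bin_features(X, max_bins)
    n_edges = np.asarray([len(e) for e in edges], dtype=np.int64)
    n_bins_max = max(len(e) + 1 for e in edges)
    tol = 1e-12 * max(1.0, float(np.sum((residuals - residuals.mean()) ** 2)))
    tree, _ = _grow_tree(
        codes,
        edges,
        n_edges,
        n_bins_max,
        residuals,
        np.arange(len(residuals), dtype=np.int64),
        max_depth,
        min_samples_leaf,
        tol,
    )
    return tree


def fit_gbm(X, y, config: GBMConfig, **kwargs) -> GBMRegressor:
    return config.estimator(**kwargs).fit(X, y)


def predict_gbm(model: GBMRegressor, X) -> np.ndarray:
    return model.predict(X)


def tree_predict(tree: _Tree, X) -> np.ndarray:
    """Predictions of a single tree (no shrinkage, no offset)."""
    X = np.asarray(X, dtype=float)
    out = np.zeros(X.shape[0])
    _hist.predict_tree(X, *tree.arrays(), out)
    return out


def random_search(
    X,
    y,
    spec: SearchSpec = SearchSpec(),
    max_bins: Optional[int] = 256,
) -> Tuple[GBMConfig, pd.DataFrame]:
    """Random hyperparameter search with inner k-fold CV on (X, y) only.

    Returns the winning configuration and the full results table (one row
    per draw with mean inner-fold RMSE and r²).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * spec.inner_k:
        raise ValueError("too few rows for the inner CV")
    rng = np.random.default_rng(spec.seed)
    draws = [
        GBMConfig(
            n_trees=int(rng.choice(np.asarray(spec.n_trees_grid))),
            learning_rate=float(rng.choice(np.asarray(spec.lr_grid))),
            max_depth=int(rng.choice(np.asarray(spec.depth_grid))),
            min_samples_leaf=int(rng.choice(np.asarray(spec.leaf_grid))),
            seed=spec.seed,
        )
        for _ in range(spec.budget)
    ]
    perm = rng.permutation(n)
    folds = np.array_split(perm, spec.inner_k)

    rows = []
    for di, cfg in enumerate(draws):
        rmses, r2s = [], []
        for f in range(spec.inner_k):
            test_idx = folds[f]
            train_idx = np.concatenate([folds[j] for j in range(spec.inner_k) if j != f])
            if len(train_idx) < 2 * cfg.min_samples_leaf:
                continue
            est = cfg.estimator(max_bins=max_bins).fit(X[train_idx], y[train_idx])
            pred = est.predict(X[test_idx])
            err = y[test_idx] - pred
            rmses.append(float(np.sqrt(np.mean(err**2))))
            sst = float(np.sum((y[test_idx] - y[test_idx].mean()) ** 2))
            r2s.append(1.0 - float(np.sum(err**2)) / sst if sst > 0 else np.nan)
        rows.append(
            {
                "draw": di,
                **asdict(cfg),
                "mean_rmse": float(np.mean(rmses)) if rmses else np.inf,
                "mean_r2": float(np.nanmean(r2s)) if r2s else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    # lowest RMSE; ties -> higher r2, then first drawn
    best_rmse = table["mean_rmse"].min()
    cand = table[table["mean_rmse"] == best_rmse]
    cand = cand[cand["mean_r2"] == cand["mean_r2"].max()]
    bi = int(cand["draw"].iloc[0])
    return draws[bi], table
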