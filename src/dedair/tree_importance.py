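"""Regression-tree modelling of the monthly DED index with impurity-based
feature importance and temporal hold-out evaluation.

The tree is CART with greedy variance-reduction splits: at each node every
(factor, threshold) pair is scored by the decrease in weighted within-node
variance, candidate thresholds being midpoints between consecutive distinct
values.  Growth stops at ``max_depth``, ``min_samples_leaf`` or zero
residual variance; leaf predictions are training-target means.  Tie-breaking
is deterministic: among equal-gain splits the lowest threshold of the
earliest factor (input order) wins, so refits on identical data reproduce
identical trees.

Importance of a factor is its share of the total weighted impurity decrease
accumulated over the nodes that split on it, normalized to sum to one —
the convention behind published importance percentages.  A seeded
permutation importance is provided as a diagnostic alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Default factor set: the seven screened dominant factors.
DEFAULT_FACTORS: tuple[str, ...] = ("AT", "PM10", "O3", "AP", "WS", "CO", "NO2")


@dataclass
class Node:
    """One tree node; leaves have ``feature is None``."""

    n: int
    value: float          # mean training target in this node (DED-index %)
    impurity: float       # variance of training targets in this node
    feature: str | None = None
    threshold: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class Hyperparameters:
    max_depth: int = 4
    min_samples_leaf: int = 3
    seed: int = 0


@dataclass
class TreeModel:
    root: Node
    factors: tuple[str, ...]
    response: str
    hyperparameters: Hyperparameters

    def predict_row(self, values) -> float:
        node = self.root
        while not node.is_leaf:
            node = node.left if values[node.feature] <= node.threshold else node.right
        return node.value

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return np.array([self.predict_row(row) for _, row in table.iterrows()])

    def depth(self) -> int:
        def _d(node: Node) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))
        return _d(self.root)

    def to_dict(self) -> dict:
        def _n(node: Node) -> dict:
            out = {"n": node.n, "value": node.value, "impurity": node.impurity}
            if not node.is_leaf:
                out.update(feature=node.feature, threshold=node.threshold,
                           left=_n(node.left), right=_n(node.right))
            return out
        return {
            "response": self.response,
            "factors": list(self.factors),
            "hyperparameters": vars(self.hyperparameters),
            "root": _n(self.root),
        }


@dataclass
class EvaluationMetrics:
    mse: float
    rmse: float
    mae: float
    split_description: str = ""


def temporal_split(table: pd.DataFrame, train_fraction: float = 0.7) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chronological split: earliest ceil(fraction*n) rows train, rest test.

    No shuffling — the hold-out is always the latest period, matching how
    a forecasting-style evaluation on monthly data must be framed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(table)
    n_train = math.ceil(train_fraction * n)
    train, test = table.iloc[:n_train], table.iloc[n_train:]
    if len(train) < 2 or len(test) < 2:
        raise ValueError(
            f"split leaves too few rows (train {len(train)}, test {len(test)})"
        )
    return train, test


def random_split(
    table: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random split, offered only as a comparison diagnostic."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(table)
    n_train = math.ceil(train_fraction * n)
    perm = rng.permutation(n)
    train = table.iloc[np.sort(perm[:n_train])]
    test = table.iloc[np.sort(perm[n_train:])]
    if len(train) < 2 or len(test) < 2:
        raise ValueError("split leaves too few rows")
    return train, test


def _variance(y: np.ndarray) -> float:
    return float(np.var(y)) if y.size else 0.0


def _best_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[int, float, float] | None:
    """Best (feature index, threshold, gain); None when no admissible split.

    Gain is the decrease in weighted impurity n_L/n*var_L + n_R/n*var_R
    relative to the parent variance.  Strict improvement is required, and
    the first encountered maximum (feature order, then ascending threshold)
    is kept, which realizes the documented tie-break.
    """
    n = y.size
    parent = _variance(y)
    best: tuple[int, float, float] | None = None
    for j in range(X.shape[1]):
        xj = X[:, j]
        order = np.argsort(xj, kind="stable")
        xs, ys = xj[order], y[order]
        # prefix sums for O(n) split scoring
        csum = np.cumsum(ys)
        csq = np.cumsum(ys ** 2)
        total, total_sq = csum[-1], csq[-1]
        distinct = np.nonzero(np.diff(xs))[0]  # split after position i
        for i in distinct:
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            var_left = csq[i] / n_left - (csum[i] / n_left) ** 2
            var_right = (total_sq - csq[i]) / n_right - ((total - csum[i]) / n_right) ** 2
            weighted = (n_left * var_left + n_right * var_right) / n
            gain = parent - weighted
            threshold = 0.5 * (xs[i] + xs[i + 1])
            if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
                best = (j, float(threshold), float(gain))
    return best


def fit_regression_tree(
    train: pd.DataFrame,
    factors: Sequence[str] = DEFAULT_FACTORS,
    response: str = "DED",
    hyperparameters: Hyperparameters | None = None,
) -> TreeModel:
    """Grow a CART regression tree on the training rows.

    A constant response yields a single-leaf tree (not an error).
    """
    hp = hyperparameters or Hyperparameters()
    factors = tuple(f for f in factors if f in train.columns)
    data = train[[response, *factors]].dropna()
    if len(data) < 2 * hp.min_samples_leaf:
        raise ValueError(
            f"need at least {2 * hp.min_samples_leaf} training rows, got {len(data)}"
        )
    X = data[list(factors)].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)

    def grow(idx: np.ndarray, depth: int) -> Node:
        yi = y[idx]
        node = Node(n=idx.size, value=float(yi.mean()), impurity=_variance(yi))
        if depth >= hp.max_depth or node.impurity <= 0 or idx.size < 2 * hp.min_samples_leaf:
            return node
        found = _best_split(X[idx], yi, hp.min_samples_leaf)
        if found is None:
            return node
        j, threshold, _gain = found
        mask = X[idx, j] <= threshold
        node.feature = factors[j]
        node.threshold = threshold
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    root = grow(np.arange(len(data)), 0)
    return TreeModel(root=root, factors=factors, response=response, hyperparameters=hp)


@dataclass
class ImportanceVector:
    importance: pd.Series
    no_splits: bool = False


def feature_importance(model: TreeModel) -> ImportanceVector:
    """Impurity-decrease importance per factor, normalized to sum to one.

    A single-leaf tree returns an all-zero vector flagged ``no_splits``.
    """
    acc = {f: 0.0 for f in model.factors}
    n_total = model.root.n

    def walk(node: Node) -> None:
        if node.is_leaf:
            return
        weighted_child = (
            node.left.n * node.left.impurity + node.right.n * node.right.impurity
        ) / node.n
        acc[node.feature] += (node.n / n_total) * (node.impurity - weighted_child)
        walk(node.left)
        walk(node.right)

    walk(model.root)
    series = pd.Series(acc, dtype=float)
    total = series.sum()
    if total <= 0:
        return ImportanceVector(importance=series, no_splits=True)
    return ImportanceVector(importance=series / total)


def permutation_importance(
    model: TreeModel, table: pd.DataFrame, n_repeats: int = 20, seed: int = 0
) -> pd.Series:
    """Mean MSE increase when each factor column is shuffled (diagnostic)."""
    rng = np.random.default_rng(seed)
    data = table[[model.response, *model.factors]].dropna()
    y = data[model.response].to_numpy(dtype=float)
    base = float(np.mean((model.predict(data) - y) ** 2))
    out = {}
    for f in model.factors:
        deltas = []
        for _ in range(n_repeats):
            shuffled = data.copy()
            shuffled[f] = rng.permutation(shuffled[f].to_numpy())
            mse = float(np.mean((model.predict(shuffled) - y) ** 2))
            deltas.append(mse - base)
        out[f] = float(np.mean(deltas))
    return pd.Series(out)


def evaluate(model: TreeModel, test: pd.DataFrame, split_description: str = "") -> EvaluationMetrics:
    """MSE, RMSE and MAE of tree predictions on held-out rows."""
    data = test[[model.response, *model.factors]].dropna()
    if data.empty:
        raise ValueError("test rows must be non-empty")
    y = data[model.response].to_numpy(dtype=float)
    pred = model.predict(data)
    mse = float(np.mean((pred - y) ** 2))
    return EvaluationMetrics(
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mae=float(np.mean(np.abs(pred - y))),
        split_description=split_description,
    )
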