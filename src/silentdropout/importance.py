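"""Random-forest regression with out-of-bag permutation importance.

A regression forest grown on bootstrap resamples ranks predictors of
acellular capillary density by mean decrease in accuracy (MDA): for each tree
t and feature X_e, the tree's accuracy on its out-of-bag (OOB) rows is
compared before (Acc_baseline_t) and after (Acc_permuted_t) permuting X_e
among those rows, and

    MDA(X_e) = (1/T) * sum_t (Acc_baseline_t - Acc_permuted_t).

"Accuracy" for a regression tree is defined here as the negative OOB mean
squared error, so that informative features yield positive MDA; the raw MDA
scale is therefore in squared target units and only the ranking is
interpretable across datasets.

Trees use variance-reduction (sum-of-squares) splits over ``mtry`` randomly
chosen candidate features, stored as flat arrays for fast vectorised
prediction.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "OOBRandomForestRegressor",
    "encode_cohort_features",
    "fit_forest",
    "oob_accuracy",
    "mda_importance",
]


@dataclass
class _Tree:
    # node arrays; feature == -1 marks a leaf whose prediction is `value`
    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.feature[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            f = self.feature[node[idx]]
            thr = self.threshold[node[idx]]
            goes_left = X[idx, f] <= thr
            node[idx] = np.where(goes_left, self.left[node[idx]], self.right[node[idx]])
            active[idx] = self.feature[node[idx]] >= 0
        return self.value[node]


def _best_split(X, y, rows, feat_candidates, min_leaf):
    """Exhaustive best split over the candidate features for one node.

    Maximises the sum-of-squares reduction; returns (feature, threshold,
    left_rows, right_rows) or None if no valid split exists.
    """
    y_node = y[rows]
    n = rows.size
    sse_parent = np.sum(y_node**2) - y_node.sum() ** 2 / n
    best = None
    best_gain = 1e-12  # require a strictly positive reduction
    for f in feat_candidates:
        x = X[rows, f]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y_node[order]
        csum = np.cumsum(ys)
        csum2 = np.cumsum(ys**2)
        total, total2 = csum[-1], csum2[-1]
        sizes = np.arange(1, n)
        # a split after position i-1 is valid only between distinct values
        valid = (xs[:-1] != xs[1:]) & (sizes >= min_leaf) & (n - sizes >= min_leaf)
        if not valid.any():
            continue
        left_sse = csum2[:-1] - csum[:-1] ** 2 / sizes
        right_sse = (total2 - csum2[:-1]) - (total - csum[:-1]) ** 2 / (n - sizes)
        gain = np.where(valid, sse_parent - left_sse - right_sse, -np.inf)
        i = int(np.argmax(gain))
        if gain[i] > best_gain:
            best_gain = gain[i]
            thr = 0.5 * (xs[i] + xs[i + 1])
            best = (int(f), float(thr))
    if best is None:
        return None
    f, thr = best
    mask = X[rows, f] <= thr
    return f, thr, rows[mask], rows[~mask]


def _grow_tree(X, y, rows, mtry, min_leaf, rng) -> _Tree:
    feature, threshold, left, right, value = [], [], [], [], []
    p = X.shape[1]

    def new_node():
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        value.append(0.0)
        return len(feature) - 1

    stack = [(new_node(), rows)]
    while stack:
        node, r = stack.pop()
        y_node = y[r]
        value[node] = float(y_node.mean())
        if r.size < 2 * min_leaf or np.ptp(y_node) == 0.0:
            continue
        cand = rng.choice(p, size=mtry, replace=False)
        split = _best_split(X, y, r, cand, min_leaf)
        if split is None:
            continue
        f, thr, r_left, r_right = split
        feature[node] = f
        threshold[node] = thr
        left[node] = new_node()
        right[node] = new_node()
        stack.append((left[node], r_left))
        stack.append((right[node], r_right))
    return _Tree(
        np.asarray(feature, dtype=np.int64),
        np.asarray(threshold, dtype=float),
        np.asarray(left, dtype=np.int64),
        np.asarray(right, dtype=np.int64),
        np.asarray(value, dtype=float),
    )


class OOBRandomForestRegressor:
    """Regression forest with per-tree OOB bookkeeping (sklearn-style).

    Parameters
    ----------
    n_trees : int
        Number of trees T.
    mtry : int or None
        Features tried per split; default ceil(p/3), the regression-forest
        convention.
    min_leaf : int
        Minimum rows per leaf.
    seed : int
        Seeds bootstrap resampling and split-feature subsampling.
    """

    def __init__(self, n_trees: int = 500, mtry: int | None = None,
                 min_leaf: int = 5, seed: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_leaf = min_leaf
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"n_trees": self.n_trees, "mtry": self.mtry,
                "min_leaf": self.min_leaf, "seed": self.seed}

    def set_params(self, **params) -> "OOBRandomForestRegressor":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, features: pd.DataFrame, target) -> "OOBRandomForestRegressor":
        X = np.asarray(features, dtype=float)
        y = np.asarray(target, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise InvalidInputError("features and target must align row-wise")
        if X.shape[0] < 2:
            raise InvalidInputError("need at least 2 rows")
        n, p = X.shape
        mtry = self.mtry if self.mtry is not None else int(np.ceil(p / 3))
        if mtry > p:
            raise InvalidConfigError(f"mtry={mtry} exceeds feature count {p}")
        self.feature_names_ = (
            list(features.columns)
            if isinstance(features, pd.DataFrame)
            else [f"x{j}" for j in range(p)]
        )
        rng = np.random.default_rng(self.seed)
        self.trees_ = []
        self.bootstrap_indices_ = []
        self.oob_indices_ = []
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), boot)
            self.trees_.append(_grow_tree(X, y, boot, mtry, self.min_leaf, rng))
            self.bootstrap_indices_.append(boot)
            self.oob_indices_.append(oob)
        self._X_train_ = X
        self._y_train_ = y
        self.mtry_ = mtry
        return self

    def predict(self, features) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(features, dtype=float)
        pred = np.zeros(X.shape[0])
        for tree in self.trees_:
            pred += tree.predict(X)
        return pred / len(self.trees_)

    def oob_accuracy(self) -> np.ndarray:
        """Per-tree baseline accuracy (negative MSE) on that tree's OOB rows.

        Trees with an empty OOB set yield NaN and are excluded downstream
        with a warning.
        """
        self._check_fitted()
        acc = np.full(len(self.trees_), np.nan)
        for t, (tree, oob) in enumerate(zip(self.trees_, self.oob_indices_)):
            if oob.size == 0:
                continue
            resid = self._y_train_[oob] - tree.predict(self._X_train_[oob])
            acc[t] = -float(np.mean(resid**2))
        if np.isnan(acc).any():
            warnings.warn(
                f"{int(np.isnan(acc).sum())} trees had empty OOB sets and are "
                "excluded from OOB averages",
                stacklevel=2,
            )
        return acc

    def mda_importance(self, seed: int | None = None) -> pd.DataFrame:
        """Permutation importance: mean decrease in accuracy per feature.

        For each (tree, feature) pair, the feature's values are permuted among
        that tree's OOB rows with one fresh seeded permutation, the OOB
        accuracy recomputed, and the per-tree drops averaged.  Returns a
        DataFrame indexed by feature with columns ``mda`` (sorted descending)
        plus the per-tree baseline mean.
        """
        self._check_fitted()
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        baseline = self.oob_accuracy()
        ok = ~np.isnan(baseline)
        p = self._X_train_.shape[1]
        drops = np.zeros((len(self.trees_), p))
        for t, (tree, oob) in enumerate(zip(self.trees_, self.oob_indices_)):
            if not ok[t]:
                continue
            X_oob = self._X_train_[oob]
            y_oob = self._y_train_[oob]
            used = np.unique(tree.feature[tree.feature >= 0])
            for f in range(p):
                perm = rng.permutation(oob.size)
                if f not in used:
                    continue  # permutation is a no-op for unused features
                X_perm = X_oob.copy()
                X_perm[:, f] = X_oob[perm, f]
                resid = y_oob - tree.predict(X_perm)
                drops[t, f] = baseline[t] - (-float(np.mean(resid**2)))
        mda = drops[ok].mean(axis=0)
        out = pd.DataFrame(
            {"mda": mda},
            index=pd.Index(self.feature_names_, name="feature"),
        )
        return out.sort_values("mda", ascending=False)

    def _check_fitted(self) -> None:
        if not hasattr(self, "trees_"):
            raise InvalidInputError("forest is not fitted; call fit first")


def encode_cohort_features(cohort: pd.DataFrame) -> pd.DataFrame:
    """Design table for the density regression: duration, mean RBG, diabetes
    status (duration > 0), diet and sex as indicator columns, and age."""
    return pd.DataFrame(
        {
            "diabetes_duration_weeks": cohort["diabetes_duration_weeks"].astype(float),
            "mean_rbg": cohort["mean_rbg"].astype(float),
            "diabetic": (cohort["diabetes_duration_weeks"] > 0).astype(float),
            "diet_high_caloric": (cohort["diet"] == "high_caloric").astype(float),
            "age_weeks": cohort["age_weeks"].astype(float),
            "sex_male": (cohort["sex"] == "male").astype(float),
        }
    )


def fit_forest(features, target, n_trees=500, mtry=None, min_leaf=5, seed=0):
    """Functional wrapper over :class:`OOBRandomForestRegressor`."""
    return OOBRandomForestRegressor(
        n_trees=n_trees, mtry=mtry, min_leaf=min_leaf, seed=seed
    ).fit(features, target)


def oob_accuracy(forest: OOBRandomForestRegressor) -> np.ndarray:
    return forest.oob_accuracy()


def mda_importance(forest: OOBRandomForestRegressor, seed: int | None = None) -> pd.DataFrame:
    return forest.mda_importance(seed=seed)
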