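"""Bagged regression-tree ensemble with permutation variable importance.

A deliberately transparent re-implementation of the regression random
forest: CART variance-reduction splits, bootstrap bagging, a random
mtry-subset of predictors eligible at each node, out-of-bag (OOB) error
estimation, and both marginal and Strobl-style *conditional* permutation
importance (permuting a predictor within strata defined by the split
points of correlated covariates, which deflates the spuriously inflated
importance of correlated predictors).

Randomness protocol (fixed so that results are reproducible bit-for-bit
and independently re-derivable):

- one ``numpy.random.default_rng(seed)`` generator drives the fit;
- for each tree, in order: bootstrap indices are drawn as
  ``rng.integers(0, n, n)``;
- the tree is grown depth-first, left child before right child; at each
  node with at least ``min_split`` samples and non-constant response,
  the eligible feature subset is drawn as
  ``rng.choice(p, size=mtry, replace=False)`` *before* split search;
- the best split maximises the reduction in the residual sum of squares;
  candidate thresholds are midpoints between consecutive distinct sorted
  values; ties are broken toward the earlier feature in the drawn subset
  and then the smaller threshold (strict improvement required).

Predictions are means over trees, hence always inside the training
response range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RegressionForest", "ImportanceReport", "permutation_importance"]

_LEAF = -1


def _grow_tree(X, y, idx, rng, mtry, min_split, arrs):
    """Grow one tree recursively; returns the node id."""
    feature, threshold, left, right, value = arrs
    node = len(feature)
    feature.append(_LEAF)
    threshold.append(0.0)
    left.append(-1)
    right.append(-1)
    yv = y[idx]
    value.append(yv.mean())
    n_node = idx.size
    if n_node < min_split or np.all(yv == yv[0]):
        return node
    p = X.shape[1]
    feats = rng.choice(p, size=mtry, replace=False)
    best_gain = 0.0
    best = None
    parent_score = yv.sum() ** 2 / n_node
    for f in feats:
        xs = X[idx, f]
        order = np.argsort(xs, kind="stable")
        xs_s = xs[order]
        ys_s = yv[order]
        distinct = xs_s[1:] > xs_s[:-1]
        if not distinct.any():
            continue
        csum = np.cumsum(ys_s)[:-1]
        total = csum[-1] + ys_s[-1]
        k = np.arange(1, n_node)
        score = csum**2 / k + (total - csum) ** 2 / (n_node - k)
        score[~distinct] = -np.inf
        kbest = int(np.argmax(score))
        gain = score[kbest] - parent_score
        if gain > best_gain:
            # split sits between sorted positions kbest and kbest+1
            best_gain = gain
            best = (f, 0.5 * (xs_s[kbest] + xs_s[kbest + 1]))
    if best is None:
        return node
    f, thr = best
    go_left = X[idx, f] <= thr
    if go_left.all() or not go_left.any():  # degenerate midpoint rounding
        return node
    feature[node] = f
    threshold[node] = thr
    left[node] = _grow_tree(X, y, idx[go_left], rng, mtry, min_split, arrs)
    right[node] = _grow_tree(X, y, idx[~go_left], rng, mtry, min_split, arrs)
    return node


@dataclass
class _Tree:
    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        node = np.zeros(n, dtype=int)
        out = np.empty(n)
        active = np.arange(n)
        while active.size:
            nd = node[active]
            is_leaf = self.feature[nd] == _LEAF
            leaf_idx = active[is_leaf]
            out[leaf_idx] = self.value[nd[is_leaf]]
            active = active[~is_leaf]
            if active.size == 0:
                break
            nd = node[active]
            go_left = X[active, self.feature[nd]] <= self.threshold[nd]
            node[active] = np.where(go_left, self.left[nd], self.right[nd])
        return out

    def split_thresholds(self, feature_idx: int) -> np.ndarray:
        """Sorted unique thresholds this tree uses for one feature."""
        m = self.feature == feature_idx
        return np.unique(self.threshold[m])


class RegressionForest:
    """Bagged CART regression forest with OOB error estimation."""

    def __init__(self, ntree: int = 500, mtry: int | None = None, min_split: int = 5, seed: int = 0):
        if ntree < 1:
            raise ValueError("ntree must be >= 1")
        self.ntree = ntree
        self.mtry = mtry
        self.min_split = min_split
        self.seed = seed
        self.trees_: list[_Tree] = []
        self.oob_sets_: list[np.ndarray] = []

    def fit(self, X, y) -> "RegressionForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if np.isnan(y).any():
            raise ValueError("missing responses are not allowed")
        mtry = self.mtry if self.mtry is not None else max(1, p // 3)
        if mtry > p:
            raise ValueError(f"mtry={mtry} exceeds the number of predictors p={p}")
        self._mtry = mtry
        rng = np.random.default_rng(self.seed)
        self.trees_ = []
        self.oob_sets_ = []
        all_idx = np.arange(n)
        for _ in range(self.ntree):
            boot = rng.integers(0, n, n)
            arrs = ([], [], [], [], [])
            _grow_tree(X, y, boot, rng, mtry, self.min_split, arrs)
            self.trees_.append(
                _Tree(*(np.asarray(a, dtype=(int if i in (0, 2, 3) else float)) for i, a in enumerate(arrs)))
            )
            self.oob_sets_.append(np.setdiff1d(all_idx, boot))
        self.X_ = X
        self.y_ = y
        self.y_range_ = (float(y.min()), float(y.max()))
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        acc = np.zeros(X.shape[0])
        for tree in self.trees_:
            acc += tree.predict(X)
        return acc / len(self.trees_)

    def oob_predictions(self) -> np.ndarray:
        """Per-sample mean prediction over trees for which it is out-of-bag.

        NaN for samples that are in-bag in every tree.
        """
        n = self.X_.shape[0]
        acc = np.zeros(n)
        cnt = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_sets_):
            if oob.size == 0:
                continue
            acc[oob] += tree.predict(self.X_[oob])
            cnt[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)

    def oob_rmse(self) -> float:
        pred = self.oob_predictions()
        ok = np.isfinite(pred)
        return float(np.sqrt(np.mean((pred[ok] - self.y_[ok]) ** 2)))


@dataclass
class ImportanceReport:
    """Per-variable permutation importance (mean OOB squared-error
    increase, ppb^2). ``importance`` floors negatives at zero for
    reporting; ``raw`` keeps the signed values."""

    table: pd.DataFrame  # columns: variable, raw, importance
    mode: str
    correlation_threshold: float | None

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("importance", ascending=False).reset_index(drop=True)

    def __getitem__(self, variable: str) -> float:
        return float(self.table.set_index("variable").loc[variable, "raw"])


def _grouped_permutation(rng, values: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Permute ``values`` uniformly at random within groups of equal code."""
    n = values.size
    rand_order = np.lexsort((rng.random(n), codes))
    stable_order = np.lexsort((np.arange(n), codes))
    out = values.copy()
    out[stable_order] = values[rand_order]
    return out


def permutation_importance(
    forest: RegressionForest,
    X=None,
    y=None,
    mode: str = "conditional",
    correlation_threshold: float = 0.2,
    max_conditioning: int = 5,
    n_permutations: int = 1,
    seed: int = 0,
    variable_names=None,
) -> ImportanceReport:
    """Marginal or conditional (Strobl-style) permutation importance.

    Marginal mode permutes each predictor freely over a tree's OOB
    samples. Conditional mode permutes it only within strata defined by
    the split points that the tree uses for covariates whose absolute
    Pearson correlation with the target predictor exceeds the threshold.
    Importance is the mean over trees of the OOB MSE increase.

    With many mutually correlated predictors the full conditioning grid
    collapses every stratum to a single observation and all importances
    vanish, so conditioning is limited to the ``max_conditioning`` most
    correlated covariates of each target predictor.
    """
    if mode not in ("marginal", "conditional"):
        raise ValueError("mode must be 'marginal' or 'conditional'")
    X = forest.X_ if X is None else np.asarray(X, dtype=float)
    y = forest.y_ if y is None else np.asarray(y, dtype=float)
    n, p = X.shape
    if variable_names is None:
        variable_names = [f"x{j}" for j in range(p)]
    if len(variable_names) != p:
        raise ValueError("variable_names length must match number of predictors")
    rng = np.random.default_rng(seed)

    corr_sets: list[np.ndarray] = []
    if mode == "conditional":
        with np.errstate(invalid="ignore"):
            cm = np.corrcoef(X, rowvar=False)
        cm = np.nan_to_num(cm, nan=0.0)
        for j in range(p):
            others = np.where((np.abs(cm[j]) > correlation_threshold))[0]
            others = others[others != j]
            if others.size > max_conditioning:
                order = np.argsort(-np.abs(cm[j, others]), kind="stable")
                others = others[order[:max_conditioning]]
            corr_sets.append(others)

    # A tree that never splits on variable j is unchanged by permuting j,
    # so it contributes an exact 0; only (tree, variable) pairs where the
    # tree uses the variable need evaluating.
    raw = np.zeros(p)
    n_used = 0
    for tree, oob in zip(forest.trees_, forest.oob_sets_):
        if oob.size < 2:
            continue
        n_used += 1
        Xo = X[oob]
        yo = y[oob]
        base_mse = np.mean((tree.predict(Xo) - yo) ** 2)
        internal = tree.feature[tree.feature != _LEAF]
        used = np.unique(internal)
        thr_map = {int(f): np.unique(tree.threshold[tree.feature == f]) for f in used}
        for j in used:
            if mode == "marginal":
                codes = np.zeros(oob.size, dtype=np.int64)
            else:
                codes = np.zeros(oob.size, dtype=np.int64)
                for z in corr_sets[j]:
                    thr = thr_map.get(int(z))
                    if thr is None:
                        continue
                    codes = codes * (thr.size + 1) + np.searchsorted(thr, Xo[:, z])
            Xp = Xo.copy()
            acc = 0.0
            for _ in range(n_permutations):
                Xp[:, j] = _grouped_permutation(rng, Xo[:, j], codes)
                acc += np.mean((tree.predict(Xp) - yo) ** 2)
            raw[j] += acc / n_permutations - base_mse
    if n_used:
        raw /= n_used
    table = pd.DataFrame(
        {"variable": variable_names, "raw": raw, "importance": np.maximum(raw, 0.0)}
    )
    return ImportanceReport(
        table=table,
        mode=mode,
        correlation_threshold=correlation_threshold if mode == "conditional" else None,
    )
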