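"""Independent brute-force reference for the bagged regression forest.

Follows the same documented randomness protocol as the production engine
(one generator; per tree: bootstrap draw, then depth-first left-first
node growth with a feature-subset draw at each splittable node) but
searches splits by naive enumeration — every split point of every
eligible feature is scored by directly summing the two children's
responses — and predicts by walking a nested-dict tree one sample at a
time. No code is shared with the production path.
"""

from __future__ import annotations

import numpy as np


def _grow(X, y, idx, rng, mtry, min_split):
    yv = y[idx]
    node = {"value": yv.mean(), "leaf": True}
    n_node = idx.size
    if n_node < min_split or np.all(yv == yv[0]):
        return node
    feats = rng.choice(X.shape[1], size=mtry, replace=False)
    parent_score = yv.sum() ** 2 / n_node
    best_gain = 0.0
    best = None
    for f in feats:
        xs = X[idx, f]
        order = np.argsort(xs, kind="stable")
        xs_s = xs[order]
        ys_s = yv[order]
        for k in range(1, n_node):  # enumerate every split position
            if not xs_s[k] > xs_s[k - 1]:
                continue
            left = ys_s[:k]
            right = ys_s[k:]
            score = left.sum() ** 2 / k + right.sum() ** 2 / (n_node - k)
            gain = score - parent_score
            if gain > best_gain:
                best_gain = gain
                best = (int(f), 0.5 * (xs_s[k - 1] + xs_s[k]))
    if best is None:
        return node
    f, thr = best
    go_left = X[idx, f] <= thr
    if go_left.all() or not go_left.any():
        return node
    node.update(
        leaf=False,
        feature=f,
        threshold=thr,
        left=_grow(X, y, idx[go_left], rng, mtry, min_split),
        right=_grow(X, y, idx[~go_left], rng, mtry, min_split),
    )
    return node


def _predict_one(node, row):
    while not node["leaf"]:
        node = node["left"] if row[node["feature"]] <= node["threshold"] else node["right"]
    return node["value"]


def oracle_oob_predictions(X, y, ntree, mtry, min_split=5, seed=0):
    """OOB predictions of the reference forest (NaN where never OOB)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(ntree):
        boot = rng.integers(0, n, n)
        trees.append((boot, _grow(X, y, boot, rng, mtry, min_split)))
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for boot, tree in trees:
        oob = np.setdiff1d(np.arange(n), boot)
        for i in oob:
            acc[i] += _predict_one(tree, X[i])
            cnt[i] += 1
    return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
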