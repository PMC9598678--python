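"""Exact path-dependent TreeSHAP for scikit-learn decision-tree ensembles.

Computes exact Shapley additive explanations of a tree's output in
polynomial time by propagating subset-weight polynomials along each
root-to-leaf path. The value function is the standard path-dependent
conditional expectation: descending a tree, a "missing" feature's split
is averaged over both children weighted by training cover, a "present"
feature follows the sample. The resulting attributions satisfy local
accuracy exactly: baseline + sum of per-feature scores equals the
model's output for every sample (here, the predicted probability of the
second class, averaged over trees for a forest).

A brute-force Shapley evaluator over all feature coalitions is provided
for verification on small trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .forest import ForestModel


@dataclass
class ShapMatrix:
    """Samples × features additive explanation scores plus the baseline."""

    values: np.ndarray
    baseline: float
    feature_names: list
    sample_ids: list | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = self.sample_ids if self.sample_ids is not None else range(self.values.shape[0])
        return pd.DataFrame(self.values, index=idx, columns=self.feature_names)

    def summary(self) -> pd.Series:
        """Mean |score| per feature, sorted descending (overall importance)."""
        s = pd.Series(
            np.abs(self.values).mean(axis=0), index=self.feature_names, name="mean_abs_shap"
        )
        return s.sort_values(ascending=False, kind="stable")


class _Path:
    __slots__ = ("d", "z", "o", "w")

    def __init__(self, d, z, o, w):
        self.d = d  # feature index
        self.z = z  # fraction of "zero" (missing) paths flowing through
        self.o = o  # fraction of "one" (present) paths
        self.w = w  # permutation-weight polynomial coefficient


def _extend(path: list[_Path], pz: float, po: float, pi: int) -> None:
    l = len(path)
    path.append(_Path(pi, pz, po, 1.0 if l == 0 else 0.0))
    for i in range(l - 1, -1, -1):
        path[i + 1].w += po * path[i].w * (i + 1) / (l + 1)
        path[i].w = pz * path[i].w * (l - i) / (l + 1)


def _unwind(path: list[_Path], i: int) -> None:
    l = len(path) - 1
    o, z = path[i].o, path[i].z
    n = path[l].w
    for j in range(l - 1, -1, -1):
        if o != 0:
            t = path[j].w
            path[j].w = n * (l + 1) / ((j + 1) * o)
            n = t - path[j].w * z * (l - j) / (l + 1)
        else:
            path[j].w = path[j].w * (l + 1) / (z * (l - j))
    for j in range(i, l):
        path[j].d, path[j].z, path[j].o = path[j + 1].d, path[j + 1].z, path[j + 1].o
    path.pop()


def _unwound_sum(path: list[_Path], i: int) -> float:
    l = len(path) - 1
    o, z = path[i].o, path[i].z
    n = path[l].w
    total = 0.0
    for j in range(l - 1, -1, -1):
        if o != 0:
            t = n * (l + 1) / ((j + 1) * o)
            total += t
            n = path[j].w - t * z * (l - j) / (l + 1)
        else:
            total += path[j].w * (l + 1) / (z * (l - j))
    return total


def _leaf_probs(tree) -> np.ndarray:
    """Per-node output: probability of class 1 (or raw value for 1-output trees)."""
    v = tree.value[:, 0, :]
    if v.shape[1] == 1:
        return v[:, 0].astype(float)
    s = v.sum(axis=1)
    return v[:, 1] / np.where(s > 0, s, 1.0)


def tree_expected_value(tree) -> float:
    """Cover-weighted mean leaf output (the TreeSHAP baseline)."""
    leaves = tree.children_left < 0
    cover = tree.weighted_n_node_samples
    vals = _leaf_probs(tree)
    return float((cover[leaves] * vals[leaves]).sum() / cover[0])


def _shap_one(tree, x: np.ndarray, phi: np.ndarray) -> None:
    left = tree.children_left
    right = tree.children_right
    feat = tree.feature
    thr = tree.threshold
    cover = tree.weighted_n_node_samples
    vals = _leaf_probs(tree)

    def recurse(node: int, path: list[_Path], pz: float, po: float, pi: int) -> None:
        path = [_Path(e.d, e.z, e.o, e.w) for e in path]
        _extend(path, pz, po, pi)
        if left[node] < 0:
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                phi[path[i].d] += w * (path[i].o - path[i].z) * vals[node]
            return
        f = int(feat[node])
        hot, cold = (left[node], right[node]) if x[f] <= thr[node] else (right[node], left[node])
        iz = io = 1.0
        k = next((i for i in range(1, len(path)) if path[i].d == f), None)
        if k is not None:
            iz, io = path[k].z, path[k].o
            _unwind(path, k)
        recurse(hot, path, iz * cover[hot] / cover[node], io, f)
        recurse(cold, path, iz * cover[cold] / cover[node], 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)


def shap_values(forest: ForestModel, X: np.ndarray | None = None) -> ShapMatrix:
    """Exact SHAP attributions of the forest's class-1 probability.

    Per-tree attributions are averaged over trees (the forest output is
    the mean of tree outputs), so local accuracy carries over to the
    ensemble.
    """
    if X is None:
        X = forest.X
    X = np.asarray(X, dtype=float)
    p = forest.n_features
    if X.ndim != 2 or X.shape[1] != p:
        raise ValueError(f"X must have {p} features to match the forest")
    ntree = len(forest.clf.estimators_)
    phi = np.zeros((X.shape[0], p))
    base = 0.0
    buf = np.zeros(p + 1)
    for est in forest.clf.estimators_:
        tree = est.tree_
        base += tree_expected_value(tree)
        for i in range(X.shape[0]):
            buf[:] = 0.0
            _shap_one(tree, X[i], buf)
            phi[i] += buf[:p]
    return ShapMatrix(values=phi / ntree, baseline=base / ntree, feature_names=list(forest.feature_names))


# ---------------------------------------------------------------------------
# brute-force oracle (exponential; verification only)


def _cond_expectation(tree, x: np.ndarray, subset: frozenset) -> float:
    """Path-dependent expectation of the tree output given features in `subset`."""
    left, right = tree.children_left, tree.children_right
    cover = tree.weighted_n_node_samples
    vals = _leaf_probs(tree)

    def rec(node: int) -> float:
        if left[node] < 0:
            return float(vals[node])
        f = int(tree.feature[node])
        if f in subset:
            child = left[node] if x[f] <= tree.threshold[node] else right[node]
            return rec(child)
        lw, rw = cover[left[node]], cover[right[node]]
        return (lw * rec(left[node]) + rw * rec(right[node])) / (lw + rw)

    return rec(0)


def brute_force_shap(tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exact Shapley values by enumerating all feature coalitions."""
    from math import factorial

    feats = list(range(n_features))
    phi = np.zeros(n_features)
    nfact = factorial(n_features)
    for j in feats:
        rest = [f for f in feats if f != j]
        for size in range(len(rest) + 1):
            for S in combinations(rest, size):
                S = frozenset(S)
                weight = factorial(len(S)) * factorial(n_features - len(S) - 1) / nfact
                gain = _cond_expectation(tree, x, S | {j}) - _cond_expectation(tree, x, S)
                phi[j] += weight * gain
    return phi
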