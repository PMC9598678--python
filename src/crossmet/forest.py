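"""Random-forest classification with structure-based importance measures.

The forest itself is scikit-learn's `RandomForestClassifier` (bootstrap
per tree, `mtry` random candidate features per split). On top of its
exposed tree structure this module computes:

* **mean minimal depth** — per tree, a feature's minimal depth is the
  depth of the shallowest node splitting on it (root = 0); features that
  a tree never uses contribute that tree's maximal depth + 1 (the
  surrogate-free fill-in convention). Smaller mean = more important.
* **OOB permutation importance Z-scores** — per tree, the drop in
  out-of-bag accuracy after permuting one feature's OOB values; the
  Z-score normalises the mean drop by its standard error across trees.
  Only features a tree actually splits on can change its predictions, so
  unused features contribute an exact zero drop without re-prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import _generate_sample_indices


@dataclass
class ForestConfig:
    """Forest hyperparameters: tree count, per-split feature subsample, seed."""

    ntree: int = 5000
    mtry: int | None = None  # default floor(sqrt(p)), the classification standard
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def resolved_mtry(self, p: int) -> int:
        if self.mtry is None:
            return max(1, int(math.floor(math.sqrt(p))))
        if self.mtry > p:
            raise ValueError(f"mtry={self.mtry} exceeds feature count {p}")
        return self.mtry


@dataclass
class ForestModel:
    """A fitted forest plus the training data and per-tree OOB bookkeeping."""

    clf: RandomForestClassifier
    X: np.ndarray
    y: np.ndarray  # encoded 0/1
    feature_names: list
    config: ForestConfig
    oob_indices: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def oob_error(self) -> float:
        """OOB misclassification rate by per-sample majority vote over trees."""
        n = self.X.shape[0]
        votes = np.zeros((n, 2))
        for est, oob in zip(self.clf.estimators_, self.oob_indices):
            if oob.size == 0:
                continue
            pred = est.predict(self.X[oob]).astype(int)
            votes[oob, pred] += 1
        voted = votes.sum(axis=1) > 0
        pred = votes.argmax(axis=1)
        return float(np.mean(pred[voted] != self.y[voted]))


def fit_forest(X, y, config: ForestConfig | None = None,
               feature_names: list | None = None) -> ForestModel:
    """Fit a bootstrap random-forest classifier and record per-tree OOB rows."""
    config = config or ForestConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2D")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("X is constant; nothing to split on")
    y01 = np.searchsorted(classes, y).astype(int)
    p = X.shape[1]
    clf = RandomForestClassifier(
        n_estimators=config.ntree,
        max_features=config.resolved_mtry(p),
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    clf.fit(X, y01)
    n = X.shape[0]
    all_idx = np.arange(n)
    oob = []
    for est in clf.estimators_:
        sampled = _generate_sample_indices(est.random_state, n, n, None)
        oob.append(np.setdiff1d(all_idx, sampled, assume_unique=False))
    names = feature_names if feature_names is not None else list(range(p))
    if len(names) != p:
        raise ValueError("feature_names length mismatch")
    return ForestModel(clf=clf, X=X, y=y01, feature_names=list(names), config=config, oob_indices=oob)


# ---------------------------------------------------------------------------
# minimal depth


@dataclass
class MinimalDepthReport:
    """Per-feature minimal-depth distribution across trees.

    ``depths[name]`` lists one minimal depth per tree in which the
    feature appears; ``table`` holds the mean minimal depth (with the
    max-depth+1 fill-in for absent trees), sorted ascending so the most
    important features come first.
    """

    depths: dict
    table: pd.DataFrame
    fill_in: str = "tree max depth + 1"


def _node_depths(tree) -> np.ndarray:
    depths = np.zeros(tree.node_count, dtype=int)
    stack = [(0, 0)]
    while stack:
        node, d = stack.pop()
        depths[node] = d
        left, right = tree.children_left[node], tree.children_right[node]
        if left >= 0:
            stack.append((left, d + 1))
            stack.append((right, d + 1))
    return depths


def minimal_depth(forest: ForestModel) -> MinimalDepthReport:
    """Mean minimal depth per feature over all trees of the forest."""
    p = forest.n_features
    depth_lists: list[list[int]] = [[] for _ in range(p)]
    fill_sum = np.zeros(p)
    for est in forest.clf.estimators_:
        tree = est.tree_
        depths = _node_depths(tree)
        max_depth = int(depths.max())
        best = np.full(p, -1, dtype=int)
        internal = tree.children_left >= 0
        for node in np.flatnonzero(internal):
            f = tree.feature[node]
            if best[f] < 0 or depths[node] < best[f]:
                best[f] = depths[node]
        for f in range(p):
            if best[f] >= 0:
                depth_lists[f].append(int(best[f]))
                fill_sum[f] += best[f]
            else:
                fill_sum[f] += max_depth + 1
    ntree = len(forest.clf.estimators_)
    mean_md = fill_sum / ntree
    table = pd.DataFrame(
        {
            "mean_minimal_depth": mean_md,
            "n_trees_present": [len(d) for d in depth_lists],
        },
        index=pd.Index(forest.feature_names, name="feature"),
    ).sort_values("mean_minimal_depth", kind="stable")
    return MinimalDepthReport(
        depths={forest.feature_names[f]: depth_lists[f] for f in range(p)},
        table=table,
    )


# ---------------------------------------------------------------------------
# OOB permutation importance


def permutation_importance_z(
    forest: ForestModel, rng: np.random.Generator | int = 0
) -> pd.Series:
    """Z-scores of the per-tree OOB accuracy drop under single-feature permutation.

    Z_j = mean_t(drop_tj) / (sd_t(drop_tj)/sqrt(ntree)); features a tree does
    not split on have an exact zero drop in that tree. Features with zero
    variance of drops get Z = 0.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X, y = forest.X, forest.y
    p = forest.n_features
    ntree = len(forest.clf.estimators_)
    drops = np.zeros((ntree, p))
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for t, (est, oob) in enumerate(zip(forest.clf.estimators_, forest.oob_indices)):
        if oob.size == 0:
            continue
        tree = est.tree_
        Xo = np.ascontiguousarray(X32[oob])
        yo = y[oob]
        leaf_class = np.argmax(tree.value[:, 0, :], axis=1)
        base_acc = float(np.mean(leaf_class[tree.apply(Xo)] == yo))
        used = np.unique(tree.feature[tree.feature >= 0])
        for f in used:
            saved = Xo[:, f].copy()
            Xo[:, f] = saved[rng.permutation(oob.size)]
            acc = float(np.mean(leaf_class[tree.apply(Xo)] == yo))
            Xo[:, f] = saved
            drops[t, f] = base_acc - acc
    mean = drops.mean(axis=0)
    sd = drops.std(axis=0, ddof=1) if ntree > 1 else np.zeros(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, mean / (sd / math.sqrt(ntree)), 0.0)
    return pd.Series(z, index=forest.feature_names, name="vim_z")
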