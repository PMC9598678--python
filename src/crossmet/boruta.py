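"""Iterative shadow-feature (Boruta) all-relevant feature selection.

Each iteration (a) appends a shadow copy of every still-active feature,
with its values permuted across observations; (b) fits a random forest
on [originals, shadows] and computes OOB permutation-importance
Z-scores; (c) counts a *hit* for each undecided feature whose Z-score
strictly exceeds the maximum shadow Z-score (MZSF); and (d) decides
feature status by an exact two-tailed binomial test (null hit
probability 0.5) at a Bonferroni-corrected level, removing rejected and
shadow features before the next round. Undecided features at the
iteration cap are reported tentative.

The Bonferroni divisor is the number of features undecided at the first
test and is held fixed across iterations so that decisions are monotone.
A tie with the MZSF counts as no hit (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd

from .forest import ForestConfig, fit_forest, permutation_importance_z

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"


def binomial_two_tailed_p(hits: int, n: int) -> float:
    """Exact two-tailed binomial p-value at null probability 0.5.

    Doubled smaller tail (capped at 1), computed by integer tail
    summation: P = 2 * min(P(X <= hits), P(X >= hits)).
    """
    if n == 0:
        return 1.0
    lo = sum(comb(n, k) for k in range(0, hits + 1))
    hi = sum(comb(n, k) for k in range(hits, n + 1))
    denom = 2**n
    return min(1.0, 2.0 * min(lo, hi) / denom)


@lru_cache(maxsize=4096)
def decision_thresholds(n_iter: int, n_features: int, alpha: float = 0.005) -> tuple[int | None, int | None]:
    """(min hits to confirm, max hits to reject) after ``n_iter`` tested iterations.

    A feature is confirmed when its Bonferroni-adjusted two-tailed p
    (divisor ``n_features``) falls below ``alpha`` on the high side, and
    rejected on the low side. Returns None for a side that cannot reach
    significance with ``n_iter`` iterations.
    """
    confirm = None
    for h in range(n_iter, -1, -1):
        if h <= n_iter / 2:
            break
        if binomial_two_tailed_p(h, n_iter) * n_features < alpha:
            confirm = h
        else:
            break
    reject = None
    for h in range(0, n_iter + 1):
        if h >= n_iter / 2:
            break
        if binomial_two_tailed_p(h, n_iter) * n_features < alpha:
            reject = h
        else:
            break
    return confirm, reject


@dataclass
class BorutaResult:
    """Outcome of a Boruta run.

    ``status`` maps each feature to confirmed/rejected/tentative;
    ``hits``/``n_tested`` hold the hit bookkeeping; ``z_history`` is one
    row per iteration of original-feature Z-scores (NaN once inactive)
    and ``mzsf_history`` the per-iteration maximum shadow Z-score.
    """

    status: pd.Series
    hits: pd.Series
    n_tested: pd.Series
    z_history: pd.DataFrame
    mzsf_history: list[float]
    alpha: float
    bonferroni_m: int
    n_iterations: int

    @property
    def confirmed(self) -> list:
        return list(self.status.index[self.status == CONFIRMED])

    @property
    def rejected(self) -> list:
        return list(self.status.index[self.status == REJECTED])

    @property
    def tentative(self) -> list:
        return list(self.status.index[self.status == TENTATIVE])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"status": self.status, "hits": self.hits, "n_tested": self.n_tested,
             "mean_z": self.z_history.mean(axis=0)}
        )


def boruta_select(
    X,
    y,
    config: ForestConfig | None = None,
    max_iter: int = 500,
    alpha: float = 0.005,
    feature_names: list | None = None,
    seed: int | None = None,
) -> BorutaResult:
    """Run the shadow-feature selection loop.

    ``config.ntree`` trees per iteration; ``config.mtry`` defaults to
    floor(sqrt(#columns of the extended matrix)). ``seed`` (default
    ``config.seed``) drives shadow permutations, per-iteration forest
    seeds and importance permutations.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    config = config or ForestConfig(ntree=500)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = list(feature_names) if feature_names is not None else list(range(p))
    if len(names) != p:
        raise ValueError("feature_names length mismatch")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    status = pd.Series(TENTATIVE, index=names, dtype=object)
    hits = pd.Series(0, index=names, dtype=int)
    tested = pd.Series(0, index=names, dtype=int)
    z_rows: list[np.ndarray] = []
    mzsf_hist: list[float] = []
    bonferroni_m = p  # undecided count at the first test, held fixed

    frozen: set = set()  # tentative features that can no longer reach a decision

    for it in range(max_iter):
        undecided = [nm for nm in status.index[status == TENTATIVE] if nm not in frozen]
        if not undecided:
            break
        active = [nm for nm in names
                  if status[nm] == CONFIRMED or nm in undecided]
        cols = [names.index(nm) for nm in active]
        Xa = X[:, cols]
        shadows = np.column_stack([Xa[rng.permutation(n), j] for j in range(Xa.shape[1])])
        Xext = np.hstack([Xa, shadows])
        it_cfg = ForestConfig(
            ntree=config.ntree,
            mtry=config.mtry,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fm = fit_forest(Xext, y, it_cfg,
                        feature_names=active + [f"shadow_{nm}" for nm in active])
        z = permutation_importance_z(fm, rng)
        z_orig = z.iloc[: len(active)]
        mzsf = float(z.iloc[len(active):].max())
        mzsf_hist.append(mzsf)
        row = np.full(p, np.nan)
        for nm, val in z_orig.items():
            row[names.index(nm)] = val
        z_rows.append(row)

        remaining = max_iter - it - 1
        for nm in undecided:
            tested[nm] += 1
            if z_orig[nm] > mzsf:  # strict: ties do not count
                hits[nm] += 1
            n_it, h = tested[nm], hits[nm]
            p_two = binomial_two_tailed_p(h, n_it) * bonferroni_m
            if p_two < alpha:
                status[nm] = CONFIRMED if h > n_it / 2 else REJECTED
                continue
            # a feature that cannot reach either threshold by max_iter is
            # necessarily tentative: stop spending forests on it
            conf_t, rej_t = decision_thresholds(n_it + remaining, bonferroni_m, alpha)
            conf_reachable = conf_t is not None and h + remaining >= conf_t
            rej_reachable = rej_t is not None and h <= rej_t
            if not conf_reachable and not rej_reachable:
                frozen.add(nm)

    z_history = pd.DataFrame(z_rows, columns=names)
    return BorutaResult(
        status=status, hits=hits, n_tested=tested, z_history=z_history,
        mzsf_history=mzsf_hist, alpha=alpha, bonferroni_m=bonferroni_m,
        n_iterations=len(mzsf_hist),
    )
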