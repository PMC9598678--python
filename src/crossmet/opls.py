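"""PLS and OPLS-DA with paired cross-validation and permutation testing.

NIPALS partial least squares (X = TP' + E, Y = UC' + F) and its
orthogonal-signal-corrected variant: OPLS removes the Y-orthogonal
structured variation into (To, Po) and forces all Y-related information
into a single predictive component (Tp, Pp), which improves
interpretability while leaving predictive power equal to PLS with the
same total number of components.

Validation follows the paired crossover structure: Q²Y = 1 − PRESS/TSS
from k-fold cross-validation whose folds partition *subjects* (both of a
subject's paired rows are held out together), and permutation tests that
relabel treatments *within* each subject — the exchangeability group of
the design. The permutation p-value uses the add-one estimator
(#{Q²_perm ≥ Q²_obs} + 1)/(n_perm + 1), whose floor with 1000
permutations is 1/1001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

_TOL = 1e-12


@dataclass
class PlsModel:
    """NIPALS PLS decomposition X = T P' + E, Y = U C' + F."""

    T: np.ndarray
    U: np.ndarray
    P: np.ndarray
    C: np.ndarray
    W: np.ndarray
    E: np.ndarray
    F: np.ndarray
    coef: np.ndarray  # p × m regression coefficients on centered data

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.coef


@dataclass
class OplsDaModel:
    """OPLS-DA model: X = Tp Pp' + To Po' + E with one predictive component."""

    Tp: np.ndarray          # L × 1 predictive scores
    Pp: np.ndarray          # p × 1 predictive loadings
    To: np.ndarray          # L × a orthogonal scores
    Po: np.ndarray          # p × a orthogonal loadings
    Wp: np.ndarray          # p predictive weights
    Wo: np.ndarray          # p × a orthogonal weights
    C: float                # Y-loading of the predictive component
    n_orth: int
    y_mean: float
    x_mean: np.ndarray
    y: np.ndarray           # centered response used in the fit
    Q2Y: float | None = None
    perm_p: float | None = None
    backscaled: pd.DataFrame | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict the (±1-coded) response for new rows of X."""
        Xr = np.asarray(X, float) - self.x_mean
        for a in range(self.n_orth):
            t_o = Xr @ self.Wo[:, a]
            Xr = Xr - np.outer(t_o, self.Po[:, a])
        return Xr @ self.Wp * self.C + self.y_mean

    @property
    def scores_orthogonality(self) -> float:
        if self.To.size == 0:
            return 0.0
        return float(np.abs(self.Tp.T @ self.To).max())


# ---------------------------------------------------------------------------
# PLS


def _dominant_column(Y: np.ndarray) -> np.ndarray:
    return Y[:, int(np.argmax(Y.var(axis=0)))].copy()


def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int, max_iter: int = 500, tol: float = 1e-10) -> PlsModel:
    """Fit a NIPALS PLS model on column-centered X and Y.

    Deterministic given input order: component signs are normalised so the
    largest-magnitude entry of each weight vector is positive.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    rank = np.linalg.matrix_rank(X)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank(X)={rank}")

    n, p = X.shape
    m = Y.shape[1]
    Xr, Yr = X.copy(), Y.copy()
    T = np.zeros((n, n_components))
    U = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    W = np.zeros((p, n_components))
    C = np.zeros((m, n_components))

    for a in range(n_components):
        if m == 1:
            w = Xr.T @ Yr[:, 0]
            nw = np.linalg.norm(w)
            if nw < _TOL:
                raise ValueError("degenerate component: X'y vanished")
            w /= nw
            t = Xr @ w
            c = (Yr.T @ t) / (t @ t)
            u = Yr[:, 0].copy()
        else:
            u = _dominant_column(Yr)
            w = np.zeros(p)
            for _ in range(max_iter):
                w_new = Xr.T @ u
                w_new /= np.linalg.norm(w_new)
                t = Xr @ w_new
                c = (Yr.T @ t) / (t @ t)
                u_new = (Yr @ c) / (c @ c)
                if np.linalg.norm(w_new - w) < tol:
                    w = w_new
                    u = u_new
                    break
                w, u = w_new, u_new
            t = Xr @ w
            c = (Yr.T @ t) / (t @ t)
        # sign convention: largest-|w| entry positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t, c, u = -w, -t, -c, -u
        pvec = (Xr.T @ t) / (t @ t)
        Xr = Xr - np.outer(t, pvec)
        Yr = Yr - np.outer(t, c)
        T[:, a], U[:, a], P[:, a], W[:, a], C[:, a] = t, u, pvec, w, c

    coef = W @ np.linalg.solve(P.T @ W, C.T)
    return PlsModel(T=T, U=U, P=P, C=C, W=W, E=Xr, F=Yr, coef=coef)


# ---------------------------------------------------------------------------
# OPLS-DA core (single response, lean arrays — reused by CV and permutations)


def _opls_core(X: np.ndarray, y: np.ndarray, n_orth: int):
    """Fit OSC-filtered OPLS on centered X, centered y.

    Returns (Wp, Wo, Po, c, Tp, To, Pp). Orthogonal extraction stops
    early if no Y-orthogonal variation remains.
    """
    n, p = X.shape
    w = X.T @ y
    nw = np.linalg.norm(w)
    if nw < _TOL:
        raise ValueError("X carries no covariance with y")
    w /= nw
    Wo = np.zeros((p, n_orth))
    Po = np.zeros((p, n_orth))
    To = np.zeros((n, n_orth))
    Xr = X.copy()
    used = 0
    for a in range(n_orth):
        t = Xr @ w
        pv = (Xr.T @ t) / (t @ t)
        w_o = pv - (w @ pv) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-10 * max(1.0, np.linalg.norm(pv)):
            break
        w_o /= n_o
        t_o = Xr @ w_o
        p_o = (Xr.T @ t_o) / (t_o @ t_o)
        Xr = Xr - np.outer(t_o, p_o)
        Wo[:, a], Po[:, a], To[:, a] = w_o, p_o, t_o
        used += 1
    Wo, Po, To = Wo[:, :used], Po[:, :used], To[:, :used]
    t_p = Xr @ w
    c = float((y @ t_p) / (t_p @ t_p))
    p_p = (Xr.T @ t_p) / (t_p @ t_p)
    return w, Wo, Po, c, t_p, To, p_p, used


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"response must contain exactly two classes, got {classes}")
    return y


def fit_opls_da(Xw: np.ndarray, y_labels: Sequence, n_orth: int = 1) -> OplsDaModel:
    """Fit OPLS-DA (1 predictive + ``n_orth`` orthogonal components).

    ``Xw`` is typically the within-subject block restricted to the two
    treatments compared; ``y_labels`` is a two-class vector (±1 or any
    two labels, mapped to ±1 in sorted order).
    """
    Xw = np.asarray(Xw, dtype=float)
    y_arr = np.asarray(y_labels).ravel()
    classes = np.unique(y_arr)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y = np.where(y_arr == classes[1], 1.0, -1.0)

    x_mean = Xw.mean(axis=0)
    X = Xw - x_mean
    y_mean = float(y.mean())
    yc = y - y_mean

    w, Wo, Po, c, t_p, To, p_p, used = _opls_core(X, yc, n_orth)
    # sign convention: largest-|w| entry positive
    j = int(np.argmax(np.abs(w)))
    if w[j] < 0:
        w, t_p, p_p, c = -w, -t_p, -p_p, -c
    model = OplsDaModel(
        Tp=t_p[:, None], Pp=p_p[:, None], To=To, Po=Po, Wp=w, Wo=Wo,
        C=c, n_orth=used, y_mean=y_mean, x_mean=x_mean, y=yc,
    )
    model.backscaled = backscale_loadings(model, Xw)
    return model


def backscale_loadings(model: OplsDaModel, X_preprocessed: np.ndarray,
                       variable_ids: Sequence | None = None) -> pd.DataFrame:
    """Per-variable (covariance, r²) against the response on the original scale.

    The loading-plot quantities: cov(x_j, y) gives the signed magnitude on
    the intensity scale and r² = squared Pearson correlation with y gives
    the colouring.
    """
    X = np.asarray(X_preprocessed, dtype=float)
    if X.shape[0] != model.y.shape[0]:
        raise ValueError("X rows do not match the fitted response length")
    y = model.y
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    cov = (Xc.T @ yc) / (n - 1)
    sx = Xc.std(axis=0, ddof=1)
    sy = yc.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(sx > 0, cov / (sx * sy), 0.0)
    ids = list(variable_ids) if variable_ids is not None else list(range(X.shape[1]))
    return pd.DataFrame({"covariance": cov, "r2": r**2}, index=ids)


# ---------------------------------------------------------------------------
# subject-aware cross-validation and permutation testing


def _subject_folds(subjects: np.ndarray, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    uniq = np.unique(subjects)
    order = rng.permutation(uniq)
    return [order[i::folds] for i in range(folds)]


def _q2_from_folds(X: np.ndarray, y: np.ndarray, subjects: np.ndarray,
                   fold_subjects: list[np.ndarray], n_orth: int) -> float:
    press = 0.0
    for held in fold_subjects:
        if held.size == 0:
            continue
        te = np.isin(subjects, held)
        tr = ~te
        ytr = y[tr]
        if np.unique(ytr).size < 2:
            raise _FoldClassError
        xm = X[tr].mean(axis=0)
        ym = ytr.mean()
        w, Wo, Po, c, _, _, _, used = _opls_core(X[tr] - xm, ytr - ym, n_orth)
        Xte = X[te] - xm
        for a in range(used):
            t_o = Xte @ Wo[:, a]
            Xte = Xte - np.outer(t_o, Po[:, a])
        yhat = Xte @ w * c + ym
        press += float(((y[te] - yhat) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


class _FoldClassError(RuntimeError):
    pass


def cross_validated_q2(
    Xw: np.ndarray,
    y: Sequence,
    subject_ids: Sequence,
    n_orth: int = 1,
    folds: int = 7,
    seed: int | np.random.Generator = 0,
    max_retries: int = 20,
) -> float:
    """Q²Y = 1 − PRESS/TSS from subject-partitioned k-fold cross-validation."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(Xw, dtype=float)
    y = _check_two_classes(y)
    subjects = np.asarray(subject_ids)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = min(folds, np.unique(subjects).size)
    for _ in range(max_retries):
        fold_subjects = _subject_folds(subjects, folds, rng)
        try:
            return _q2_from_folds(X, y, subjects, fold_subjects, n_orth)
        except _FoldClassError:
            continue
    raise RuntimeError("could not draw folds with both classes in every training set")


def select_n_orth(
    Xw: np.ndarray,
    y: Sequence,
    subject_ids: Sequence,
    candidates: Sequence[int] = (0, 1, 2, 3),
    folds: int = 7,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Pick the orthogonal-component count maximising cross-validated Q²Y.

    Returns (best n_orth, {n_orth: Q²Y}); ties resolve to the smaller
    model. Each candidate is scored with the same fold seed so the
    comparison is paired.
    """
    scores = {
        a: cross_validated_q2(Xw, y, subject_ids, n_orth=a, folds=folds, seed=seed)
        for a in candidates
    }
    best = max(sorted(scores), key=lambda a: scores[a])
    return best, scores


def _permute_within_subjects(y: np.ndarray, subjects: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    out = y.copy()
    for s in np.unique(subjects):
        rows = np.flatnonzero(subjects == s)
        out[rows] = y[rows[rng.permutation(rows.size)]]
    return out


def permutation_test(
    Xw: np.ndarray,
    y: Sequence,
    subject_ids: Sequence,
    n_orth: int = 1,
    folds: int = 7,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, np.ndarray]:
    """Within-subject permutation test of the cross-validated Q²Y.

    Returns (perm_p, q2_observed, q2_permuted). Labels are permuted within
    each subject (the exchangeable unit of a crossover); p uses the
    add-one estimator so the smallest reportable value is 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(Xw, dtype=float)
    y = _check_two_classes(y)
    subjects = np.asarray(subject_ids)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q2_obs = cross_validated_q2(X, y, subjects, n_orth=n_orth, folds=folds, seed=rng)
    q2_perm = np.empty(n_perm)
    for i in range(n_perm):
        yp = _permute_within_subjects(y, subjects, rng)
        if np.unique(yp).size < 2:  # pathological tiny designs
            q2_perm[i] = -np.inf
            continue
        q2_perm[i] = cross_validated_q2(X, yp, subjects, n_orth=n_orth, folds=folds, seed=rng)
    p = (int(np.sum(q2_perm >= q2_obs)) + 1) / (n_perm + 1)
    return p, q2_obs, q2_perm
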