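"""Figure rendering: back-scaled loading plots, SHAP beeswarms, Boruta boxplots.

All functions return the matplotlib Figure and optionally save it; they
consume the tabular outputs of the analysis modules and hold no logic of
their own.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import LineCollection

from .boruta import BorutaResult, CONFIRMED
from .treeshap import ShapMatrix


def plot_backscaled_loadings(backscaled: pd.DataFrame, path: str | Path | None = None,
                             title: str = "") -> plt.Figure:
    """Covariance line coloured by r² (blue = weak, red = strong)."""
    labels = None
    try:
        x = np.asarray(backscaled.index, dtype=float)
    except (TypeError, ValueError):  # named variables, not a ppm axis
        labels = [str(i) for i in backscaled.index]
        x = np.arange(len(backscaled), dtype=float)
    cov = backscaled["covariance"].to_numpy()
    r2 = backscaled["r2"].to_numpy()
    pts = np.array([x, cov]).T.reshape(-1, 1, 2)
    segs = np.concatenate([pts[:-1], pts[1:]], axis=1)
    lc = LineCollection(segs, cmap="coolwarm", norm=plt.Normalize(0, 1))
    lc.set_array(r2[:-1])
    fig, ax = plt.subplots(figsize=(10, 3.5))
    ax.add_collection(lc)
    ax.set_xlim(x.max(), x.min())  # NMR convention: ppm decreasing rightward
    pad = 0.05 * (cov.max() - cov.min() + 1e-12)
    ax.set_ylim(cov.min() - pad, cov.max() + pad)
    if labels is None:
        ax.set_xlabel("chemical shift (ppm)")
    else:
        ax.set_xticks(x, labels)
        plt.setp(ax.get_xticklabels(), rotation=45, ha="left", fontsize=7)
        ax.set_xlabel("variable")
    ax.set_ylabel("cov(X, y)")
    ax.set_title(title)
    fig.colorbar(lc, ax=ax, label="r$^2$")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig


def plot_shap_beeswarm(shap: ShapMatrix, X: np.ndarray, path: str | Path | None = None,
                       max_features: int = 15, rng_seed: int = 0) -> plt.Figure:
    """Per-sample SHAP scores by feature, coloured by the feature value."""
    order = shap.summary().index[:max_features]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(order) + 1.5))
    rng = np.random.default_rng(rng_seed)
    df = shap.to_frame()
    Xdf = pd.DataFrame(np.asarray(X), columns=shap.feature_names)
    for k, name in enumerate(reversed(list(order))):
        vals = df[name].to_numpy()
        col = Xdf[name].to_numpy()
        rng_jitter = rng.normal(0, 0.07, size=vals.size)
        rngd = col - col.min()
        denom = rngd.max() if rngd.max() > 0 else 1.0
        ax.scatter(vals, k + rng_jitter, c=rngd / denom, cmap="viridis", s=12)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(range(len(order)), list(reversed(list(order))))
    ax.set_xlabel("SHAP value (impact on prediction)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig


def plot_boruta(result: BorutaResult, path: str | Path | None = None,
                directions: pd.Series | None = None) -> plt.Figure:
    """Boxplots of per-iteration importance Z-scores for confirmed features."""
    conf = result.confirmed
    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(conf) + 2), 4))
    if conf:
        data = [result.z_history[c].dropna().to_numpy() for c in conf]
        bp = ax.boxplot(data, tick_labels=[str(c) for c in conf], showmeans=True)
        if directions is not None:
            for i, c in enumerate(conf, start=1):
                d = directions.get(c, 0)
                color = "green" if d > 0 else "red" if d < 0 else "grey"
                ax.plot(i, ax.get_ylim()[1], marker="s", color=color, clip_on=False)
    ax.set_ylabel("VIM Z-score")
    ax.set_title(f"Boruta-confirmed features (n={len(conf)})")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig


def plot_pls_map(pls_map: dict, path: str | Path | None = None) -> plt.Figure:
    """Two-block PLS association biplot (metabolites + clinical variables)."""
    xc, yc = pls_map["x_coords"], pls_map["y_coords"]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(xc.iloc[:, 0], xc.iloc[:, 1], c="tab:blue", label="metabolites")
    ax.scatter(yc.iloc[:, 0], yc.iloc[:, 1], c="tab:red", marker="^", label="clinical")
    for df in (xc, yc):
        for name, row in df.iterrows():
            ax.annotate(str(name), (row.iloc[0], row.iloc[1]), fontsize=7)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.legend()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig
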