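"""Metabolite–clinical association analysis.

Spearman rank correlations between every (clinical variable, metabolite)
pair with a fixed Bonferroni significance threshold, plus a two-block
PLS latent-variable map that represents the joint association structure
(metabolites as predictors, clinical panel as multi-response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .opls import fit_pls

#: Default significance threshold: Bonferroni-style 0.05 / 25 assessed variables.
SPEARMAN_ALPHA = 0.002


@dataclass
class CorrelationTable:
    """rho / p / significance grids: rows = clinical variables, columns = metabolites."""

    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float

    def formatted(self) -> pd.DataFrame:
        """Report-style table: 'r = .. p = ..' for significant cells, NS otherwise."""
        out = self.rho.copy().astype(object)
        for i in self.rho.index:
            for j in self.rho.columns:
                if bool(self.significant.loc[i, j]):
                    out.loc[i, j] = f"r = {self.rho.loc[i, j]:.3f} p = {self.p.loc[i, j]:.3f}"
                else:
                    out.loc[i, j] = "NS"
        return out

    def save(self, path, sep: str = "\t") -> None:
        self.formatted().to_csv(path, sep=sep, index_label="clinical")


def spearman_table(
    metabolite_matrix: pd.DataFrame,
    clinical_matrix: pd.DataFrame,
    alpha: float = SPEARMAN_ALPHA,
) -> CorrelationTable:
    """All-pairs Spearman correlations with a fixed significance cutoff.

    rho uses average ranks for ties; p comes from the t approximation.
    Constant columns yield an undefined rho, reported as NaN/NS.
    """
    if len(metabolite_matrix) != len(clinical_matrix):
        raise ValueError("matrices must have aligned rows")
    if len(metabolite_matrix) < 4:
        raise ValueError("need at least 4 paired observations")
    mets = list(metabolite_matrix.columns)
    clin = list(clinical_matrix.columns)
    rho = pd.DataFrame(np.nan, index=clin, columns=mets)
    pval = pd.DataFrame(np.nan, index=clin, columns=mets)
    for c in clin:
        yv = clinical_matrix[c].to_numpy(dtype=float)
        for m in mets:
            xv = metabolite_matrix[m].to_numpy(dtype=float)
            if np.std(xv) == 0 or np.std(yv) == 0:
                continue  # undefined: left NaN -> NS
            r, p = stats.spearmanr(xv, yv)
            rho.loc[c, m] = r
            pval.loc[c, m] = p
    sig = (pval < alpha).fillna(False)
    return CorrelationTable(rho=rho, p=pval, significant=sig, alpha=alpha)


def two_block_pls(
    metabolite_matrix: pd.DataFrame,
    clinical_matrix: pd.DataFrame,
    n_components: int = 2,
) -> dict:
    """Two-block PLS association map.

    Fits PLS with centered metabolites as X and the centered clinical
    block as multi-response Y, returning variable coordinates on the
    first ``n_components`` latent components for a joint biplot, plus the
    per-component latent covariances cov(t_a, u_a).
    """
    X = metabolite_matrix.to_numpy(dtype=float)
    Y = clinical_matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    if clinical_matrix.shape[1] < 2:
        raise ValueError("clinical block must have at least two variables")
    model = fit_pls(Xc, Yc, n_components)
    n = X.shape[0]
    # cov(t_a, Y-side latent direction): u is stored as Y c/(c'c), so scale
    # by ||c|| to get the unit-direction projection — for the first
    # component this equals the leading singular value of cov(X, Y).
    latent_cov = [
        float(model.T[:, a] @ model.U[:, a] * np.linalg.norm(model.C[:, a]) / (n - 1))
        for a in range(n_components)
    ]
    return {
        "x_coords": pd.DataFrame(
            model.W[:, :n_components],
            index=metabolite_matrix.columns,
            columns=[f"comp{a + 1}" for a in range(n_components)],
        ),
        "y_coords": pd.DataFrame(
            model.C[:, :n_components],
            index=clinical_matrix.columns,
            columns=[f"comp{a + 1}" for a in range(n_components)],
        ),
        "latent_covariance": latent_cov,
        "model": model,
    }
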