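"""End-to-end orchestration: preprocessing → variation splitting →
OPLS-DA with validation → forest-based feature selection → consolidated
per-metabolite reports, for every configured treatment pair.

The OPLS stage runs on the highest-resolution matrix available (spectral
grid when spectra are present, otherwise the metabolite table); the
machine-learning stage always runs on the named-metabolite table, matching
the granularity at which forests and SHAP are interpretable. Every
silent default (normalisation off, excision window, n_orth, ...) is
logged so gap-filling decisions stay auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .boruta import BorutaResult, boruta_select
from .dataset import CrossoverDataset
from .forest import ForestConfig, MinimalDepthReport, fit_forest, minimal_depth
from .multilevel import split_variation
from .opls import OplsDaModel, backscale_loadings, fit_opls_da, permutation_test
from .peaks import primary_peak_regions, serum_peak_library
from .spectra import (
    FeatureMatrix,
    WATER_REGION,
    digitize,
    integrate_regions,
    normalize_pqn,
    normalize_total_area,
    reference_shift,
    remove_regions,
)
from .associations import CorrelationTable, SPEARMAN_ALPHA, spearman_table, two_block_pls
from .treeshap import ShapMatrix, shap_values

log = logging.getLogger("crossmet")

DEFAULT_PAIRS = (("FOOT", "VOO"), ("FOO", "VOO"), ("FOOT", "FOO"))


@dataclass
class AnalysisConfig:
    """All pipeline knobs with study defaults.

    ``ntree=5000``, ``n_perm=1000``, ``boruta_iter=500`` are the
    full-scale analysis settings; desk-scale runs usually pass smaller
    values.
    """

    treatment_pairs: tuple = DEFAULT_PAIRS
    bin_width: float | str = "full"
    grid_step: float = 0.002
    water_region: tuple[float, float] = WATER_REGION
    reference: bool = True
    normalization: str = "none"  # "none" | "total_area" | "pqn"
    n_orth: int = 1
    folds: int = 7
    n_perm: int = 1000
    ntree: int = 5000
    boruta_iter: int = 500
    boruta_alpha: float = 0.005
    spearman_alpha: float = SPEARMAN_ALPHA
    compute_shap: bool = True
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True, default=str)


@dataclass
class PairwiseReport:
    """Consolidated outcome of one treatment-pair comparison."""

    pair: tuple[str, str]
    q2y: float
    perm_p: float
    n_orth: int
    opls: OplsDaModel
    backscaled: pd.DataFrame          # per-OPLS-variable covariance / r2
    metabolite_table: pd.DataFrame    # consolidated per-metabolite summary
    min_depth: MinimalDepthReport
    shap: ShapMatrix | None
    boruta: BorutaResult
    oob_error: float

    def summary(self) -> dict:
        return {
            "pair": list(self.pair),
            "Q2Y": self.q2y,
            "perm_p": self.perm_p,
            "n_orth": self.n_orth,
            "oob_error": self.oob_error,
            "boruta_confirmed": [str(f) for f in self.boruta.confirmed],
        }

    def save(self, out_dir: str | Path, sep: str = "\t") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"{self.pair[0]}_vs_{self.pair[1]}"
        with open(out / f"{tag}_summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=1, sort_keys=True)
        self.backscaled.to_csv(out / f"{tag}_backscaled.tsv", sep=sep, index_label="variable")
        self.metabolite_table.to_csv(out / f"{tag}_metabolites.tsv", sep=sep, index_label="metabolite")
        self.min_depth.table.to_csv(out / f"{tag}_minimal_depth.tsv", sep=sep)
        if self.shap is not None:
            self.shap.to_frame().to_csv(out / f"{tag}_shap.tsv", sep=sep, index_label="sample")
        self.boruta.table().to_csv(out / f"{tag}_boruta.tsv", sep=sep, index_label="feature")


def preprocess_dataset(ds: CrossoverDataset, config: AnalysisConfig) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Spectra → (OPLS feature matrix, per-metabolite table).

    Reference to the anomeric anchor, excise the water band, digitise to
    the configured grid/bins, and integrate primary peak regions into the
    named-metabolite table. For datasets that already carry a feature
    table (no spectra), both outputs are that table.
    """
    if not ds.spectra:
        fm = ds.feature_matrix()
        return fm, ds.features.copy()
    log.info("preprocess: reference=%s water_region=%s bin_width=%s normalization=%s",
             config.reference, config.water_region, config.bin_width, config.normalization)
    spectra = ds.spectra
    if config.reference:
        spectra = [reference_shift(s) for s in spectra]
    spectra = [remove_regions(s, [config.water_region]) for s in spectra]
    fm = digitize(spectra, config.bin_width, grid_step=config.grid_step)
    if config.normalization == "total_area":
        log.warning("total-area normalisation ON (non-default)")
        fm = normalize_total_area(fm)
    elif config.normalization == "pqn":
        log.warning("probabilistic-quotient normalisation ON (non-default)")
        fm = normalize_pqn(fm)
    elif config.normalization != "none":
        raise ValueError(f"unknown normalization {config.normalization!r}")
    regions = primary_peak_regions(serum_peak_library())
    met = integrate_regions(spectra, regions).to_frame()
    met.index = pd.Index([s.sample_id for s in spectra], name="sample_id")
    # order rows to match the design table
    met = met.loc[[i for i in ds.design.index]]
    order = [list(fm.sample_ids).index(i) for i in ds.design.index]
    fm = FeatureMatrix(fm.X[order], list(fm.variable_ids), [fm.sample_ids[i] for i in order])
    return fm, met


def _direction_of_change(met_pair: pd.DataFrame, design: pd.DataFrame, pair: tuple[str, str]) -> pd.Series:
    """Sign of the within-subject paired mean difference, pair[0] − pair[1]."""
    a, b = pair
    da = met_pair[design["treatment"] == a].copy()
    db = met_pair[design["treatment"] == b].copy()
    da.index = design.loc[design["treatment"] == a, "subject"]
    db.index = design.loc[design["treatment"] == b, "subject"]
    diff = (da - db.loc[da.index]).mean(axis=0)
    return np.sign(diff).astype(int)


def run_pairwise(ds: CrossoverDataset, pair: tuple[str, str],
                 config: AnalysisConfig | None = None) -> PairwiseReport:
    """Run the full pairwise comparison for one treatment pair."""
    config = config or AnalysisConfig()
    sub = ds.subset_pair(pair)
    if sub.design.empty:
        raise ValueError(f"no complete subjects for pair {pair}")
    fm, met = preprocess_dataset(sub, config)
    subjects = sub.design["subject"].to_numpy()
    y = np.where(sub.design["treatment"].to_numpy() == pair[0], 1.0, -1.0)

    # multilevel split of both matrices; OPLS + forests act on the within block
    vs = split_variation(fm.X, subjects)
    vs_met = split_variation(met.to_numpy(dtype=float), subjects)
    Xw, Xw_met = vs.Xw, vs_met.Xw

    model = fit_opls_da(Xw, y, n_orth=config.n_orth)
    model.backscaled = backscale_loadings(model, Xw, variable_ids=fm.variable_ids)
    perm_p, q2, _ = permutation_test(
        Xw, y, subjects, n_orth=config.n_orth, folds=config.folds,
        n_perm=config.n_perm, seed=config.seed,
    )
    model.Q2Y, model.perm_p = q2, perm_p

    met_names = list(met.columns)
    fc = ForestConfig(ntree=config.ntree, seed=config.seed)
    forest = fit_forest(Xw_met, y, fc, feature_names=met_names)
    md = minimal_depth(forest)
    shap = shap_values(forest) if config.compute_shap else None
    boruta = boruta_select(
        Xw_met, y, ForestConfig(ntree=config.ntree, seed=config.seed),
        max_iter=config.boruta_iter, alpha=config.boruta_alpha,
        feature_names=met_names,
    )

    if shap is not None and boruta.confirmed:
        # consistency check (logged, never fatal): confirmed features are
        # expected to sit above the median mean-|SHAP|
        s = shap.summary()
        below = [f for f in boruta.confirmed if s.get(f, 0.0) < s.median()]
        if below:
            log.warning("confirmed features below median mean-|SHAP|: %s", below)

    met_backscaled = backscale_loadings(model, Xw_met, variable_ids=met_names)
    table = pd.DataFrame(index=pd.Index(met_names, name="metabolite"))
    table["covariance"] = met_backscaled["covariance"]
    table["r2"] = met_backscaled["r2"]
    table["mean_minimal_depth"] = md.table["mean_minimal_depth"]
    if shap is not None:
        table["mean_abs_shap"] = shap.summary()
    table["boruta_status"] = boruta.status
    table["boruta_hits"] = boruta.hits
    table["direction"] = _direction_of_change(met, sub.design, pair)
    table = table.sort_values("r2", ascending=False, kind="stable")

    return PairwiseReport(
        pair=pair, q2y=q2, perm_p=perm_p, n_orth=model.n_orth, opls=model,
        backscaled=model.backscaled, metabolite_table=table, min_depth=md,
        shap=shap, boruta=boruta, oob_error=forest.oob_error(),
    )


def run_associations(ds: CrossoverDataset, config: AnalysisConfig | None = None) -> dict:
    """Metabolite–clinical associations on post-intervention values pooled
    across treatments (restrict with ``ds.subset_pair`` for per-arm runs)."""
    config = config or AnalysisConfig()
    if ds.clinical is None:
        raise ValueError("dataset has no clinical table")
    if ds.features is not None:
        met = ds.features
    else:
        _, met = preprocess_dataset(ds, config)
    table = spearman_table(met, ds.clinical, alpha=config.spearman_alpha)
    pls_map = two_block_pls(met, ds.clinical)
    return {"spearman": table, "pls_map": pls_map}


def run_all(ds: CrossoverDataset, config: AnalysisConfig | None = None) -> dict:
    """All configured pairwise comparisons plus the association analysis."""
    config = config or AnalysisConfig()
    reports = {}
    for pair in config.treatment_pairs:
        log.info("pairwise comparison %s vs %s", *pair)
        reports[pair] = run_pairwise(ds, tuple(pair), config)
    out = {"pairwise": reports}
    if ds.clinical is not None:
        out["associations"] = run_associations(ds, config)
    return out
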