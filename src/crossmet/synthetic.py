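"""Synthetic crossover NMR metabolomics generator with known ground truth.

Emulates a complete randomized crossover feeding trial: ``n_subjects``
volunteers each measured once after every one of K treatments. True
metabolite concentrations follow a two-level Gaussian model

    conc[sample, m] = baseline_m + u[subject, m] + e[sample, m] + planted shift,

with subject effects ``u ~ N(0, sigma_between²)`` and within-subject
residuals ``e ~ N(0, sigma_within²)``. Treatment effects are planted
additively on the concentration scale *before* spectral rendering, so
peak overlap downstream is an honest nuisance. Effect sizes are given on
the paired-difference scale (Cohen's d_z): a planted effect d for pair
(A, B) shifts the A arm by +d·√2·σ_within/2 and the B arm by the
opposite, making the paired mean difference divided by the paired SD
recover d in expectation.

Clinical covariates are induced by a Gaussian copula on the standardized
true concentrations, so requested Spearman rank correlations between a
metabolite and a clinical variable are controlled directly
(ρ_latent = 2·sin(π·r_s/6)).

Sequence (period) effects default to zero, with an optional additive
knob for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CrossoverDataset
from .peaks import PeakDef, library_metabolites, serum_peak_library
from .spectra import Spectrum

#: Default baseline concentration per serum metabolite (arbitrary units,
#: loosely proportional to typical serum NMR signal contributions).
DEFAULT_BASELINES: dict[str, float] = {
    "isoleucine": 0.6,
    "valine": 0.9,
    "3-hydroxybutyrate": 0.7,
    "lactate": 2.0,
    "alanine": 1.2,
    "acetate": 0.5,
    "acetone": 0.5,
    "acetoacetate": 0.5,
    "glutamine": 1.5,
    "citrate": 0.8,
    "dimethylamine": 0.5,
    "creatine": 0.8,
    "creatinine": 0.8,
    "dimethylsulfone": 0.5,
    "glycine": 1.0,
    "glucose": 5.0,
    "histidine": 0.7,
}
_FALLBACK_BASELINE = 1.0

#: Clinical marginals (mean, SD) used to place latent normals on a
#: realistic scale for a hypercholesterolemic cohort.
CLINICAL_MARGINALS: dict[str, tuple[float, float]] = {
    "HDL-C": (53.0, 13.0),
    "ApoA1": (1.4, 0.2),
    "ApoB100": (1.2, 0.2),
    "total_cholesterol": (228.0, 40.0),
    "LDL-C": (148.0, 29.0),
    "triglycerides": (120.0, 40.0),
    "glucose_plasma": (91.0, 12.0),
    "cardiovascular_risk": (5.0, 2.4),
    "endothelial_function": (170.0, 150.0),
}


class ConfigurationError(ValueError):
    """Simulation configuration violates an invariant."""


@dataclass
class SimulationConfig:
    """Study conditions for one simulated crossover trial.

    ``planted_effects`` maps an ordered treatment pair to
    {metabolite: signed paired effect size d}; positive d means the
    first-named treatment has the higher concentration.
    ``clinical_loadings`` maps (metabolite, clinical variable) to a
    target Spearman rank correlation.
    """

    n_subjects: int = 33
    treatments: tuple[str, ...] = ("VOO", "FOO", "FOOT")
    planted_effects: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    sigma_between: float = 0.15
    sigma_within: float = 0.075
    clinical_loadings: dict[tuple[str, str], float] = field(default_factory=dict)
    ppm_range: tuple[float, float] = (0.5, 9.0)
    n_points: int = 4096
    noise_sd: float = 0.005
    peak_library: list[PeakDef] = field(default_factory=serum_peak_library)
    baselines: dict[str, float] = field(default_factory=dict)
    period_effect: float = 0.0
    render_spectra: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.treatments) < 2:
            raise ConfigurationError("need at least 2 treatments (K >= 2)")
        if len(set(self.treatments)) != len(self.treatments):
            raise ConfigurationError("treatment labels must be unique")
        if self.sigma_between < 0:
            raise ConfigurationError("sigma_between must be >= 0")
        if self.sigma_within <= 0:
            raise ConfigurationError("sigma_within must be > 0")
        if not self.peak_library:
            raise ConfigurationError("peak library is empty")
        mets = set(library_metabolites(self.peak_library))
        for pair, effects in self.planted_effects.items():
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ConfigurationError(f"invalid treatment pair {pair}")
            for t in pair:
                if t not in self.treatments:
                    raise ConfigurationError(f"unknown treatment {t!r} in planted_effects")
            for m in effects:
                if m not in mets:
                    raise ConfigurationError(f"unknown metabolite {m!r} in planted_effects")
        clin = set(CLINICAL_MARGINALS)
        for (m, c), r in self.clinical_loadings.items():
            if m not in mets:
                raise ConfigurationError(f"unknown metabolite {m!r} in clinical_loadings")
            if c not in clin:
                raise ConfigurationError(f"unknown clinical variable {c!r}")
            if not -1 < r < 1:
                raise ConfigurationError(f"target rank correlation must be in (-1, 1), got {r}")

    @property
    def metabolites(self) -> list[str]:
        return library_metabolites(self.peak_library)


def default_study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default emulated trial: 33 subjects, 3 olive-oil arms, planted
    concentration shifts for the treatment-responsive serum metabolites
    (amino acids and methylamines down, ketone bodies up under the
    phenol-enriched oils) and metabolite–lipid rank correlations typical
    of a hypercholesterolemic cohort."""
    planted = {
        # phenol-enriched oils lower amino acids / methylamines vs control oil
        ("FOOT", "VOO"): {
            "glutamine": -2.0, "creatinine": -2.0, "histidine": -2.0,
            "creatine": -1.5, "dimethylamine": -1.5, "glycine": -1.5,
            "dimethylsulfone": -1.5, "valine": -1.0, "alanine": -1.0,
        },
        ("FOO", "VOO"): {
            "glutamine": -2.0, "creatinine": -2.0, "histidine": -2.0,
            "creatine": -1.5, "dimethylamine": -1.5, "alanine": -1.5,
            "acetone": 2.0, "3-hydroxybutyrate": 1.5, "valine": -1.0,
        },
        ("FOO", "FOOT"): {
            "acetone": 1.5, "acetoacetate": 1.5, "3-hydroxybutyrate": 1.5,
            "glutamine": -1.0, "alanine": -1.0, "isoleucine": -1.0,
        },
    }
    loadings = {
        ("glutamine", "HDL-C"): 0.48,
        ("glutamine", "triglycerides"): -0.55,
        ("glutamine", "glucose_plasma"): -0.44,
        ("glutamine", "cardiovascular_risk"): -0.40,
        ("histidine", "triglycerides"): -0.33,
        ("creatine", "HDL-C"): 0.41,
        ("isoleucine", "ApoA1"): -0.30,
    }
    cfg = dict(planted_effects=planted, clinical_loadings=loadings, seed=seed)
    cfg.update(overrides)
    return SimulationConfig(**cfg)


# ---------------------------------------------------------------------------


def render_spectrum(
    concentrations: dict[str, float],
    peak_library: list[PeakDef],
    ppm_axis: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
) -> Spectrum:
    """Render a spectrum as the concentration-weighted sum of Lorentzians.

    Intensity at each point is Σ_peaks level·relative_height·L(center, width)
    plus i.i.d. Gaussian noise of SD ``noise_sd``.
    """
    if not peak_library:
        raise ValueError("peak library is empty")
    known = set(library_metabolites(peak_library))
    unknown = set(concentrations) - known
    if unknown:
        raise KeyError(f"metabolites not in peak library: {sorted(unknown)}")
    ppm_axis = np.asarray(ppm_axis, dtype=float)
    y = np.zeros_like(ppm_axis)
    for p in peak_library:
        level = concentrations.get(p.metabolite_name, 0.0)
        if level != 0.0:
            y += level * p.profile(ppm_axis)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    return Spectrum(ppm_axis.copy(), y, sample_id)


def _treatment_offsets(cfg: SimulationConfig) -> pd.DataFrame:
    """Per (metabolite, treatment) additive concentration shifts.

    Planted effect d on pair (A, B) is split ±δ/2 with δ = d·√2·σ_within
    (the SD of a paired difference), so the paired Cohen's d_z equals d.
    """
    off = pd.DataFrame(
        0.0, index=cfg.metabolites, columns=list(cfg.treatments), dtype=float
    )
    for (a, b), effects in cfg.planted_effects.items():
        for m, d in effects.items():
            delta = d * math.sqrt(2.0) * cfg.sigma_within
            off.loc[m, a] += delta / 2.0
            off.loc[m, b] -= delta / 2.0
    return off


def _latin_square_periods(n_subjects: int, treatments: tuple[str, ...]) -> list[list[str]]:
    """Cyclic Latin-square treatment sequences, subjects rotated through K orders."""
    k = len(treatments)
    return [[treatments[(i + j) % k] for j in range(k)] for i in range(n_subjects)]


def _clinical_table(
    cfg: SimulationConfig, conc: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Gaussian-copula clinical table with requested rank correlations."""
    n = len(conc)
    z_met = (conc - conc.mean()) / conc.std(ddof=0).replace(0.0, 1.0)
    by_var: dict[str, list[tuple[str, float]]] = {c: [] for c in CLINICAL_MARGINALS}
    for (m, c), r in cfg.clinical_loadings.items():
        by_var[c].append((m, 2.0 * math.sin(math.pi * r / 6.0)))
    cols = {}
    for c, (mu, sd) in CLINICAL_MARGINALS.items():
        load = by_var[c]
        rho2 = sum(r * r for _, r in load)
        if rho2 >= 1.0:
            raise ConfigurationError(
                f"clinical variable {c!r}: loadings imply latent variance > 1"
            )
        z = rng.normal(size=n) * math.sqrt(1.0 - rho2)
        for m, r in load:
            z = z + r * z_met[m].to_numpy()
        cols[c] = mu + sd * z
    return pd.DataFrame(cols, index=conc.index)


def generate_dataset(config: SimulationConfig) -> CrossoverDataset:
    """Simulate one complete crossover study.

    Returns K·n_subjects samples (each subject measured once per
    treatment) with design, clinical and ground-truth tables, plus
    rendered spectra and/or the metabolite feature table depending on
    ``config.render_spectra``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.treatments)
    mets = cfg.metabolites
    base = np.array(
        [cfg.baselines.get(m, DEFAULT_BASELINES.get(m, _FALLBACK_BASELINE)) for m in mets]
    )
    offsets = _treatment_offsets(cfg)

    sequences = _latin_square_periods(cfg.n_subjects, cfg.treatments)
    rows, subj_ids, treat_ids, periods, sample_ids = [], [], [], [], []
    subj_effect = rng.normal(0.0, cfg.sigma_between, size=(cfg.n_subjects, len(mets)))
    for i in range(cfg.n_subjects):
        sid = f"S{i + 1:02d}"
        for period, treat in enumerate(sequences[i], start=1):
            e = rng.normal(0.0, cfg.sigma_within, size=len(mets))
            conc = base + subj_effect[i] + e + offsets[treat].to_numpy()
            if cfg.period_effect != 0.0:
                conc = conc + cfg.period_effect * (period - (k + 1) / 2.0) * cfg.sigma_within
            rows.append(conc)
            subj_ids.append(sid)
            treat_ids.append(treat)
            periods.append(period)
            sample_ids.append(f"{sid}_{treat}")

    conc_df = pd.DataFrame(rows, index=sample_ids, columns=mets)
    design = pd.DataFrame(
        {"subject": subj_ids, "treatment": treat_ids, "period": periods},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    clinical = _clinical_table(cfg, conc_df, rng)

    spectra = []
    if cfg.render_spectra:
        ppm = np.linspace(cfg.ppm_range[0], cfg.ppm_range[1], cfg.n_points)
        for sid_row in sample_ids:
            spectra.append(
                render_spectrum(
                    conc_df.loc[sid_row].to_dict(), cfg.peak_library, ppm,
                    noise_sd=cfg.noise_sd, rng=rng, sample_id=sid_row,
                )
            )

    truth = {
        "planted_effects": {
            f"{a}|{b}": dict(eff) for (a, b), eff in cfg.planted_effects.items()
        },
        "sigma_between": cfg.sigma_between,
        "sigma_within": cfg.sigma_within,
        "true_concentrations": {
            "index": sample_ids,
            "columns": mets,
            "data": conc_df.to_numpy().tolist(),
        },
        "clinical_loadings": {f"{m}|{c}": r for (m, c), r in cfg.clinical_loadings.items()},
        "seed": cfg.seed,
    }
    return CrossoverDataset(
        design=design,
        features=None if cfg.render_spectra else conc_df,
        clinical=clinical,
        spectra=spectra,
        truth=truth,
    )


def true_concentrations(ds: CrossoverDataset) -> pd.DataFrame:
    """Recover the generator's true concentration table from the truth sidecar."""
    if ds.truth is None or "true_concentrations" not in ds.truth:
        raise ValueError("dataset carries no ground truth")
    t = ds.truth["true_concentrations"]
    return pd.DataFrame(t["data"], index=t["index"], columns=t["columns"])
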