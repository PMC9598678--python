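"""Crossover dataset container: features + design + clinical tables."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .spectra import FeatureMatrix, Spectrum, read_spectrum, write_spectrum


@dataclass
class CrossoverDataset:
    """A complete crossover study: one row per subject × treatment.

    ``design`` is indexed by sample id with columns ``subject``,
    ``treatment`` and ``period``; ``features`` (samples × variables) and
    ``clinical`` (samples × clinical variables) share that index.
    ``spectra`` holds the raw per-sample traces when the study was
    acquired (or simulated) at spectral resolution. ``truth`` carries the
    simulation ground truth (planted effects, true concentrations) and is
    ``None`` for real data.
    """

    design: pd.DataFrame
    features: pd.DataFrame | None = None
    clinical: pd.DataFrame | None = None
    spectra: list[Spectrum] = field(default_factory=list)
    truth: dict | None = None

    def __post_init__(self) -> None:
        req = {"subject", "treatment", "period"}
        missing = req - set(self.design.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        for name, tab in (("features", self.features), ("clinical", self.clinical)):
            if tab is not None and not tab.index.equals(self.design.index):
                raise ValueError(f"{name} index does not match design index")

    @property
    def treatments(self) -> list[str]:
        return sorted(self.design["treatment"].unique())

    @property
    def n_subjects(self) -> int:
        return self.design["subject"].nunique()

    def feature_matrix(self) -> FeatureMatrix:
        if self.features is None:
            raise ValueError("dataset has no feature table; digitise spectra first")
        return FeatureMatrix.from_frame(self.features)

    def subset_pair(self, pair: tuple[str, str]) -> "CrossoverDataset":
        """Rows for the two treatments of `pair`, restricted to subjects with both."""
        a, b = pair
        if a == b:
            raise ValueError(f"treatment pair must name two distinct treatments, got {pair}")
        present = set(self.design["treatment"])
        for t in pair:
            if t not in present:
                raise ValueError(f"treatment {t!r} not present in design")
        d = self.design[self.design["treatment"].isin(pair)]
        counts = d.groupby("subject")["treatment"].nunique()
        keep_subj = counts[counts == 2].index
        d = d[d["subject"].isin(keep_subj)]
        idx = d.index
        return CrossoverDataset(
            design=d.copy(),
            features=None if self.features is None else self.features.loc[idx].copy(),
            clinical=None if self.clinical is None else self.clinical.loc[idx].copy(),
            spectra=[s for s in self.spectra if s.sample_id in set(idx)],
            truth=self.truth,
        )

    # -- text round trip ---------------------------------------------------

    def save(self, out_dir: str | Path, sep: str = "\t") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.design.to_csv(out / "design.tsv", sep=sep, index_label="sample_id")
        if self.features is not None:
            self.features.to_csv(out / "features.tsv", sep=sep, index_label="sample_id")
        if self.clinical is not None:
            self.clinical.to_csv(out / "clinical.tsv", sep=sep, index_label="sample_id")
        if self.spectra:
            sp = out / "spectra"
            sp.mkdir(exist_ok=True)
            for s in self.spectra:
                write_spectrum(s, sp / f"{s.sample_id}.txt")
        if self.truth is not None:
            with open(out / "truth.json", "w") as fh:
                json.dump(self.truth, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, in_dir: str | Path, sep: str = "\t") -> "CrossoverDataset":
        src = Path(in_dir)
        design = pd.read_csv(src / "design.tsv", sep=sep, index_col=0)
        design.index = design.index.astype(str)

        def _opt(name: str) -> pd.DataFrame | None:
            p = src / name
            if not p.exists():
                return None
            df = pd.read_csv(p, sep=sep, index_col=0)
            df.index = df.index.astype(str)
            return df

        spectra = []
        sp = src / "spectra"
        if sp.is_dir():
            spectra = [read_spectrum(p) for p in sorted(sp.glob("*.txt"))]
        truth = None
        if (src / "truth.json").exists():
            truth = json.loads((src / "truth.json").read_text())
        return cls(design, _opt("features.tsv"), _opt("clinical.tsv"), spectra, truth)
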