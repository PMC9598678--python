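"""Spectral data model and preprocessing.

A :class:`Spectrum` is one sample's 1D ¹H-NMR trace on a ppm axis. The
preprocessing surface mirrors routine serum workflows: chemical-shift
referencing to the alpha-glucose anomeric proton, excision of the
residual-water band, and digitisation of a spectrum collection into a
samples × variables feature matrix (full-resolution common grid or
fixed-width bin integrals).

Axes are stored ascending internally; readers accept either orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .peaks import ALPHA_GLUCOSE_PPM

#: Default residual-water excision band (ppm). Community-standard window
#: for water-suppression artefacts in serum; deliberately below the
#: 5.223 ppm referencing anchor.
WATER_REGION = (4.5, 5.1)


class ReferencingError(RuntimeError):
    """No usable anchor peak found in the requested search window."""


@dataclass
class Spectrum:
    """One sample's ppm axis and intensities.

    Invariants: equal-length arrays and a strictly monotone ppm axis
    (stored ascending).
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be equal-length 1D arrays")
        d = np.diff(self.ppm)
        if np.all(d < 0):  # descending input: flip to ascending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            raise ValueError("ppm axis must be strictly monotone")

    def __len__(self) -> int:
        return self.ppm.size


@dataclass
class FeatureMatrix:
    """Samples × variables data matrix with aligned identifiers."""

    X: np.ndarray
    variable_ids: list
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D")
        if self.X.shape != (len(self.sample_ids), len(self.variable_ids)):
            raise ValueError("X shape does not match sample/variable ids")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.sample_ids, columns=self.variable_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(df.to_numpy(dtype=float), list(df.columns), [str(i) for i in df.index])


# ---------------------------------------------------------------------------
# preprocessing operations


def reference_shift(
    s: Spectrum,
    anchor_search_window: tuple[float, float] = (ALPHA_GLUCOSE_PPM - 0.05, ALPHA_GLUCOSE_PPM + 0.05),
    target_ppm: float = ALPHA_GLUCOSE_PPM,
) -> Spectrum:
    """Translate the ppm axis so the tallest peak in the window sits at `target_ppm`.

    Raises :class:`ReferencingError` (tagged with the sample id) when the
    window contains no interior local maximum.
    """
    lo, hi = min(anchor_search_window), max(anchor_search_window)
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if mask.sum() < 3:
        raise ReferencingError(f"{s.sample_id}: anchor window [{lo}, {hi}] has <3 points")
    idx = np.flatnonzero(mask)
    seg = s.intensity[idx]
    k = int(np.argmax(seg))
    if k in (0, len(seg) - 1) or not (seg[k] > seg[k - 1] and seg[k] > seg[k + 1]):
        raise ReferencingError(
            f"{s.sample_id}: no interior local maximum in anchor window [{lo}, {hi}]"
        )
    apex = s.ppm[idx[k]]
    shift = target_ppm - apex
    if shift == 0.0:
        return s
    return replace(s, ppm=s.ppm + shift)


def remove_regions(s: Spectrum, regions: Sequence[tuple[float, float]] = (WATER_REGION,)) -> Spectrum:
    """Delete axis points falling inside any of the given ppm intervals."""
    if not regions:
        return s
    keep = np.ones(len(s), dtype=bool)
    for lo, hi in regions:
        lo, hi = min(lo, hi), max(lo, hi)
        keep &= ~((s.ppm >= lo) & (s.ppm <= hi))
    if not keep.any():
        raise ValueError(f"{s.sample_id}: region removal would delete the entire axis")
    return replace(s, ppm=s.ppm[keep], intensity=s.intensity[keep])


def _interp(s: Spectrum, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, s.ppm, s.intensity)


def _cum_trapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


def digitize(
    spectra: Sequence[Spectrum],
    bin_width: float | str = "full",
    grid_step: float = 0.001,
) -> FeatureMatrix:
    """Digitise spectra into a feature matrix.

    ``bin_width="full"`` interpolates every spectrum onto a common
    ``grid_step``-spaced grid over the shared ppm range (variable ids =
    grid ppm). A numeric ``bin_width`` b instead integrates the
    piecewise-linear spectrum over consecutive width-b windows (variable
    ids = bin centres); the sum of bin integrals then equals the
    full-range trapezoid integral by construction.
    """
    if not spectra:
        raise ValueError("no spectra supplied")
    lo = max(s.ppm[0] for s in spectra)
    hi = min(s.ppm[-1] for s in spectra)
    if hi <= lo:
        raise ValueError("spectra ppm axes do not overlap")
    sample_ids = [s.sample_id for s in spectra]

    if isinstance(bin_width, str):
        if bin_width != "full":
            raise ValueError(f"bin_width must be numeric or 'full', got {bin_width!r}")
        grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
        grid = grid[grid <= hi]
        X = np.stack([_interp(s, grid) for s in spectra])
        return FeatureMatrix(X, [float(g) for g in grid], sample_ids)

    b = float(bin_width)
    if b <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor((hi - lo) / b + 1e-9))
    if n_bins < 1:
        raise ValueError("bin_width larger than the shared ppm range")
    edges = lo + b * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for s in spectra:
        # integrate the piecewise-linear interpolant exactly between edges
        x = np.union1d(s.ppm[(s.ppm >= lo) & (s.ppm <= hi)], edges)
        y = _interp(s, x)
        cum = _cum_trapz(y, x)
        at_edges = np.interp(edges, x, cum)
        rows.append(np.diff(at_edges))
    return FeatureMatrix(np.stack(rows), [float(c) for c in centers], sample_ids)


def integrate_regions(
    spectra: Sequence[Spectrum], regions: dict[str, tuple[float, float]]
) -> FeatureMatrix:
    """Named-region trapezoid integrals, one variable per region.

    The standard route from preprocessed spectra to a per-metabolite
    table when integration windows (e.g. primary peak regions) are known.
    """
    names = list(regions)
    rows = []
    for s in spectra:
        vals = []
        for name in names:
            lo, hi = regions[name]
            lo, hi = min(lo, hi), max(lo, hi)
            x = np.union1d(s.ppm[(s.ppm >= lo) & (s.ppm <= hi)], [lo, hi])
            x = x[(x >= s.ppm[0]) & (x <= s.ppm[-1])]
            if x.size < 2:
                vals.append(0.0)
                continue
            y = _interp(s, x)
            vals.append(float(np.trapezoid(y, x)))
        rows.append(vals)
    return FeatureMatrix(np.asarray(rows), names, [s.sample_id for s in spectra])


# ---------------------------------------------------------------------------
# optional normalisers (off by default; the default pipeline applies none)


def normalize_total_area(fm: FeatureMatrix, target: float = 1.0) -> FeatureMatrix:
    """Scale every row to a common total signal (total-area normalisation)."""
    sums = fm.X.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("cannot total-area normalise a zero-sum sample")
    return FeatureMatrix(fm.X / sums * target, list(fm.variable_ids), list(fm.sample_ids))


def normalize_pqn(fm: FeatureMatrix) -> FeatureMatrix:
    """Probabilistic-quotient normalisation against the median spectrum."""
    ta = normalize_total_area(fm)
    ref = np.median(ta.X, axis=0)
    keep = ref > 0
    quot = np.median(ta.X[:, keep] / ref[keep], axis=1, keepdims=True)
    return FeatureMatrix(ta.X / quot, list(fm.variable_ids), list(fm.sample_ids))


# ---------------------------------------------------------------------------
# text I/O


def read_spectrum(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column (ppm, intensity) whitespace/comma-delimited file."""
    path = Path(path)
    arr = np.loadtxt(path, delimiter=None if _sniff_ws(path) else ",")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return Spectrum(arr[:, 0], arr[:, 1], sample_id or path.stem)


def _sniff_ws(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                return "," not in line
    return True


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([s.ppm, s.intensity]), fmt="%.6f\t%.8g")


def write_feature_matrix(fm: FeatureMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write variables as columns; ppm bin centres formatted to 4 decimals."""
    cols = [f"{v:.4f}" if isinstance(v, float) else str(v) for v in fm.variable_ids]
    pd.DataFrame(fm.X, index=fm.sample_ids, columns=cols).to_csv(path, sep=sep, index_label="sample_id")


def read_feature_matrix(path: str | Path, sep: str = "\t") -> FeatureMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    cols: list = []
    for c in df.columns:
        try:
            cols.append(float(c))
        except ValueError:
            cols.append(c)
    return FeatureMatrix(df.to_numpy(dtype=float), cols, [str(i) for i in df.index])
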