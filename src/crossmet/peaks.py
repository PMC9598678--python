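"""Lorentzian peak definitions and the default serum metabolite library.

The library covers the small-molecule resonances routinely profiled in
CPMG serum spectra (branched-chain amino acids, ketone bodies, organic
acids, methylamines, glucose). Chemical shifts are nominal literature
positions; each metabolite is reduced to one or two singlet-like peaks —
enough to make peak overlap an honest nuisance without modelling
J-coupling fine structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Anomeric proton of alpha-glucose, the conventional serum referencing anchor.
ALPHA_GLUCOSE_PPM = 5.223


@dataclass(frozen=True)
class PeakDef:
    """One Lorentzian resonance of a metabolite.

    Parameters
    ----------
    metabolite_name
        Metabolite the resonance belongs to.
    center_ppm
        Chemical shift of the peak maximum (ppm).
    width_ppm
        Lorentzian half-width at half-maximum (ppm); must be > 0.
    relative_height
        Peak height per unit concentration (unitless, >= 0).
    """

    metabolite_name: str
    center_ppm: float
    width_ppm: float
    relative_height: float = 1.0

    def __post_init__(self) -> None:
        if self.width_ppm <= 0:
            raise ValueError(f"width_ppm must be > 0, got {self.width_ppm}")
        if self.relative_height < 0:
            raise ValueError("relative_height must be >= 0")

    def profile(self, ppm: np.ndarray) -> np.ndarray:
        """Height-normalised Lorentzian evaluated on `ppm`."""
        g2 = self.width_ppm**2
        return self.relative_height * g2 / ((ppm - self.center_ppm) ** 2 + g2)


_W = 0.004  # default half-width (ppm), ~2 Hz at 500 MHz

#: (metabolite, [(center_ppm, rel_height), ...]) for the serum panel.
_SERUM_PEAKS: list[tuple[str, list[tuple[float, float]]]] = [
    ("isoleucine", [(0.936, 0.8), (1.010, 0.5)]),
    ("valine", [(0.986, 0.8), (1.030, 0.8)]),
    ("3-hydroxybutyrate", [(1.200, 0.9), (4.130, 0.3)]),
    ("lactate", [(1.330, 1.0), (4.110, 0.4)]),
    ("alanine", [(1.480, 1.0)]),
    ("acetate", [(1.920, 1.0)]),
    ("acetone", [(2.230, 1.0)]),
    ("acetoacetate", [(2.280, 1.0)]),
    ("glutamine", [(2.140, 0.6), (2.450, 1.0)]),
    ("citrate", [(2.540, 0.8), (2.660, 0.8)]),
    ("dimethylamine", [(2.720, 1.0)]),
    ("creatine", [(3.040, 1.0), (3.930, 0.6)]),
    ("creatinine", [(3.050, 0.9), (4.060, 0.5)]),
    ("dimethylsulfone", [(3.150, 1.0)]),
    ("glycine", [(3.560, 1.0)]),
    ("glucose", [(3.470, 0.7), (ALPHA_GLUCOSE_PPM, 1.0)]),
    ("histidine", [(7.050, 0.8), (7.770, 0.6)]),
]


def serum_peak_library(width_ppm: float = _W) -> list[PeakDef]:
    """Default 17-metabolite serum library (34 Lorentzian resonances)."""
    return [
        PeakDef(name, c, width_ppm, h)
        for name, peaks in _SERUM_PEAKS
        for c, h in peaks
    ]


def library_metabolites(library: list[PeakDef]) -> list[str]:
    """Unique metabolite names in library order of first appearance."""
    seen: dict[str, None] = {}
    for p in library:
        seen.setdefault(p.metabolite_name, None)
    return list(seen)


def primary_peak_regions(
    library: list[PeakDef], half_widths: float = 5.0
) -> dict[str, tuple[float, float]]:
    """Integration window around each metabolite's tallest resonance.

    Windows extend ``half_widths`` Lorentzian half-widths either side of
    the peak centre, which captures ~87% of the analytic peak area at the
    default 5 half-widths.
    """
    best: dict[str, PeakDef] = {}
    for p in library:
        cur = best.get(p.metabolite_name)
        if cur is None or p.relative_height > cur.relative_height:
            best[p.metabolite_name] = p
    return {
        name: (p.center_ppm - half_widths * p.width_ppm,
               p.center_ppm + half_widths * p.width_ppm)
        for name, p in best.items()
    }


def synthetic_peak_library(
    names: list[str],
    ppm_range: tuple[float, float] = (0.5, 9.0),
    width_ppm: float = _W,
    include_anchor: bool = True,
) -> list[PeakDef]:
    """Evenly spaced single-peak library for arbitrary variable names.

    Used for simulation scenarios that need many non-overlapping nuisance
    variables rather than realistic serum chemistry. The alpha-glucose
    anchor is appended (as metabolite "glucose") unless already present or
    disabled, so chemical-shift referencing stays exercisable.
    """
    lo, hi = ppm_range
    centers = np.linspace(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo), len(names))
    lib = [PeakDef(n, float(c), width_ppm, 1.0) for n, c in zip(names, centers)]
    if include_anchor and "glucose" not in names:
        lib.append(PeakDef("glucose", ALPHA_GLUCOSE_PPM, width_ppm, 1.0))
    return lib
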