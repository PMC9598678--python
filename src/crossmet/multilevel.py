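"""Multilevel variation splitting for crossover designs.

Two consecutive centerings decompose a samples × variables matrix X into
an offset term, a between-subject block and a within-subject block:

    X = Xm + Xb + Xw

The first centering removes the column means over all L rows (Xm is the
rank-1 offset); the second centers each subject's K rows around that
subject's mean, leaving Xw, the within-subject (treatment) variation.
Every row of Xb is its subject's centered mean, so Xb carries the
between-subject (biological) variation. For balanced designs Xb ⟂ Xw in
the Frobenius inner product.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class VariationSplit:
    """The (Xm, Xb, Xw) decomposition of a crossover feature matrix."""

    Xm: np.ndarray
    Xb: np.ndarray
    Xw: np.ndarray
    subject_index: list
    K: int | None

    @property
    def L(self) -> int:
        return self.Xm.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.Xm + self.Xb + self.Xw

    def save(self, out_dir: str | Path, variable_ids: Sequence | None = None, sep: str = "\t") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cols = list(variable_ids) if variable_ids is not None else list(range(self.Xm.shape[1]))
        for name, block in (("Xm", self.Xm), ("Xb", self.Xb), ("Xw", self.Xw)):
            pd.DataFrame(block, index=self.subject_index, columns=cols).to_csv(
                out / f"{name}.tsv", sep=sep, index_label="subject"
            )


def split_variation(
    X: np.ndarray, subject_ids: Sequence, allow_unbalanced: bool = False
) -> VariationSplit:
    """Split X into offset, between-subject and within-subject blocks.

    Requires a complete crossover (every subject with the same K >= 2
    rows) unless ``allow_unbalanced`` is set, in which case per-subject
    row counts K_i are used (each subject still needs >= 2 rows). The
    decomposition reconstructs X exactly: the operations are two exact
    centering subtractions.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2D")
    subject_ids = list(subject_ids)
    if len(subject_ids) != X.shape[0]:
        raise ValueError("subject_ids length must equal the number of rows of X")

    counts: dict = {}
    for s in subject_ids:
        counts[s] = counts.get(s, 0) + 1
    sizes = set(counts.values())
    if min(sizes) < 2:
        bad = [s for s, c in counts.items() if c < 2]
        raise ValueError(f"subjects with a single row have no within-subject variation: {bad}")
    if len(sizes) > 1 and not allow_unbalanced:
        raise ValueError(
            f"unbalanced design (row counts per subject: {sorted(sizes)}); "
            "pass allow_unbalanced=True to use per-subject K_i"
        )
    K = sizes.pop() if len(sizes) == 1 else None

    x_m = X.mean(axis=0)
    Xm = np.broadcast_to(x_m, X.shape).copy()
    Xc = X - x_m

    Xb = np.empty_like(Xc)
    Xw = np.empty_like(Xc)
    for s in counts:
        rows = [i for i, sid in enumerate(subject_ids) if sid == s]
        x_bi = Xc[rows].mean(axis=0)
        Xb[rows] = x_bi
        Xw[rows] = Xc[rows] - x_bi
    return VariationSplit(Xm=Xm, Xb=Xb, Xw=Xw, subject_index=subject_ids, K=K)
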