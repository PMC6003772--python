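"""Ligation-extent statistics from extension-product intensity ladders.

A ladder records one band intensity per product length (0..N substrates
added, N = number of ligation junctions).  The extent of ligation at
junction j is the fraction of molecules that, having reached junction j,
were ligated through it — a survival ratio of tail sums.  This definition
makes the per-junction extents and the full-length yield mutually
consistent: the product of all extents telescopes exactly to the
full-length fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean


@dataclass
class Ladder:
    """Band intensities indexed by number of substrates added (0..N)."""

    intensities: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.intensities, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a ladder needs at least lengths 0 and 1")
        if v.min() < 0:
            raise ValueError("intensities must be non-negative")
        if v.max() <= 0:
            raise ValueError("ladder has no signal (all intensities zero)")
        self.intensities = v

    @property
    def n_junctions(self) -> int:
        return self.intensities.size - 1

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "n_added": np.arange(self.intensities.size),
            "intensity": self.intensities,
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Ladder":
        df = pd.read_csv(path, sep="\t").sort_values("n_added")
        if not np.array_equal(df["n_added"].to_numpy(), np.arange(len(df))):
            raise ValueError("ladder TSV must cover lengths 0..N contiguously")
        return cls(df["intensity"].to_numpy(dtype=float))


def junction_extents(ladder: Ladder) -> np.ndarray:
    """Extent of ligation at each junction (1..N).

    extent_j = (sum of intensities at lengths >= j) / (sum at lengths >= j-1).
    Junctions past the point where no molecules remain see a 0/0 ratio;
    these are reported as extent 0 and flagged with a warning (nothing
    arrived there, so nothing was ligated through).
    """
    tail = np.cumsum(ladder.intensities[::-1])[::-1]  # tail[m] = sum_{k>=m} I_k
    exhausted = tail[:-1] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        extents = np.where(exhausted, 0.0, tail[1:] / np.where(exhausted, 1.0, tail[:-1]))
    if exhausted.any():
        warnings.warn("ladder exhausted before the final junction: "
                      f"{int(exhausted.sum())} junctions saw no molecules")
    return extents


def mean_extent(extents: np.ndarray, method: str = "geometric") -> float:
    """Average extent of ligation across junctions (geometric by default)."""
    e = np.asarray(extents, dtype=float)
    if method == "arithmetic":
        return float(e.mean())
    if method != "geometric":
        raise ValueError("method must be 'geometric' or 'arithmetic'")
    if (e == 0).any():
        warnings.warn("zero junction extent: geometric mean is 0")
        return 0.0
    return float(gmean(e))


def full_length_yield(ladder: Ladder) -> float:
    """Fraction of all molecules that reached full length."""
    return float(ladder.intensities[-1] / ladder.intensities.sum())
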