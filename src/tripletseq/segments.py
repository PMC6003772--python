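"""Reference-based fidelity of long synthesised RNA segments.

Full-length sequencing reads of a synthesised segment are compared to the
expected product sequence: reads with too many mutations (default > 9) are
excluded as unrelated products, per-position base fidelities are tabulated
over the kept reads, and overall synthesis fidelity is summarised as the
geometric mean over the *internal* triplet positions — the synthesised
positions excluding the primer and the final triplet, which is an error
hot-spot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .io import sequences

_DEFAULT_FLOOR = 1e-9


@dataclass(frozen=True)
class SegmentReference:
    """Expected product sequence with its primer span.

    The first `primer_len` positions come from the primer and are not
    synthesised; the remaining span must be a whole number of triplets.
    """

    sequence: str
    primer_len: int

    def __post_init__(self) -> None:
        if not 0 <= self.primer_len < len(self.sequence):
            raise ValueError("primer_len out of range")
        if (len(self.sequence) - self.primer_len) % 3 != 0:
            raise ValueError("synthesised span must be a multiple of 3")

    @property
    def synthesised_len(self) -> int:
        return len(self.sequence) - self.primer_len


@dataclass
class FilterResult:
    kept: list
    excluded_fraction: float
    n_input: int
    n_mutation_excluded: int
    n_length_excluded: int


def filter_reads(reads, reference: SegmentReference, max_mutations: int = 9) -> FilterResult:
    """Keep reads with at most `max_mutations` substitutions vs the reference.

    Reads of a different length than the reference cannot be compared
    base-by-base and are excluded under a separate tally.  The excluded
    fraction covers both exclusion classes, relative to all input reads.
    """
    ref = np.frombuffer(reference.sequence.encode(), dtype=np.uint8)
    kept, n_mut, n_len = [], 0, 0
    all_reads = list(reads)
    for r in all_reads:
        seq = r if isinstance(r, str) else r.seq
        if len(seq) != ref.size:
            n_len += 1
            continue
        mm = int((np.frombuffer(seq.encode(), dtype=np.uint8) != ref).sum())
        if mm > max_mutations:
            n_mut += 1
        else:
            kept.append(r)
    n = len(all_reads)
    if n == 0:
        warnings.warn("empty read set: excluded fraction undefined")
        frac = float("nan")
    else:
        frac = (n_mut + n_len) / n
    return FilterResult(kept, frac, n, n_mut, n_len)


def per_position_fidelity(reads, reference: SegmentReference) -> np.ndarray:
    """Percent of reads matching the reference base, per synthesised position.

    Only positions after the primer are reported (the primer is not a
    product of synthesis).
    """
    seqs = list(sequences(reads))
    if not seqs:
        raise ValueError("need at least one read")
    ref = np.frombuffer(reference.sequence.encode(), dtype=np.uint8)
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), ref.size)
    match = (mat == ref).mean(axis=0)
    return 100.0 * match[reference.primer_len:]


def internal_triplet_average(
    fidelities_pct: np.ndarray,
    reference: SegmentReference,
    floor: float = _DEFAULT_FLOOR,
) -> float:
    """Geometric mean (%) over internal triplet positions.

    `fidelities_pct` covers the synthesised (non-primer) span; the final
    triplet's three positions are excluded as an error hot-spot.  Computed
    in log space with zero values floored.
    """
    v = np.asarray(fidelities_pct, dtype=float)
    if v.shape != (reference.synthesised_len,):
        raise ValueError(
            f"expected {reference.synthesised_len} fidelity values, got {v.size}"
        )
    if v.size < 6:
        raise ValueError("need at least one internal triplet")
    internal = v[:-3] / 100.0
    return 100.0 * float(gmean(np.maximum(internal, floor)))


def segment_fidelity(
    reads,
    reference: SegmentReference,
    max_mutations: int = 9,
) -> dict:
    """Full segment analysis: filter, per-position fidelity, internal average."""
    flt = filter_reads(reads, reference, max_mutations)
    if not flt.kept:
        raise ValueError("no reads survive the mutation filter")
    per_pos = per_position_fidelity(flt.kept, reference)
    return {
        "per_position_pct": per_pos,
        "internal_average_pct": internal_triplet_average(per_pos, reference),
        "excluded_fraction": flt.excluded_fraction,
        "n_kept": len(flt.kept),
        "n_mutation_excluded": flt.n_mutation_excluded,
        "n_length_excluded": flt.n_length_excluded,
    }


def per_position_frame(reference: SegmentReference, fidelities_pct: np.ndarray) -> pd.DataFrame:
    syn = reference.sequence[reference.primer_len:]
    return pd.DataFrame({
        "position": np.arange(1, len(syn) + 1),
        "ref_base": list(syn),
        "fidelity_pct": np.asarray(fidelities_pct, dtype=float),
    })
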