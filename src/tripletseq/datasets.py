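"""Bundled example dataset: measured per-position fidelities of a
ribozyme-synthesised 24-nt RNA segment.

The segment was synthesised by a triplet polymerase ribozyme from a 6-nt
primer (positions 1-6 of the product) under three substrate regimes:

* ``defined_triplets`` — the six specific triplets encoding the segment;
* ``random_pool`` — the full random 64-triplet pool;
* ``low_g_random_pool`` — a compositionally biased (reduced-G) random pool.

Each regime gives one percent-fidelity value per synthesised position
(18 positions = 6 triplets); the final triplet is an error hot-spot and is
excluded from the internal-triplet average.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .segments import SegmentReference

SEGMENT_SEQUENCE = "GCCAUCAAAGCUUGAGAGCAUCUU"
SEGMENT_PRIMER_LEN = 6

REGIMES = ("defined_triplets", "random_pool", "low_g_random_pool")


def synthesised_segment_reference() -> SegmentReference:
    """Reference for the bundled synthesised-segment dataset."""
    return SegmentReference(SEGMENT_SEQUENCE, SEGMENT_PRIMER_LEN)


def synthesised_segment_fidelities() -> pd.DataFrame:
    """Long-format table: regime, position, ref_base, fidelity_pct."""
    path = resources.files("tripletseq.data") / "synthesised_segment_fidelities.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def regime_fidelities(regime: str) -> "pd.Series":
    """Per-position fidelity vector (%) for one substrate regime."""
    df = synthesised_segment_fidelities()
    sub = df[df["regime"] == regime].sort_values("position")
    if sub.empty:
        raise KeyError(f"unknown regime {regime!r}; choose from {REGIMES}")
    return sub["fidelity_pct"].reset_index(drop=True)
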