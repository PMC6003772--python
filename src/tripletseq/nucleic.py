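"""Small RNA-alphabet helpers shared across the package.

The canonical internal alphabet is RNA (A, C, G, U); DNA-style input is
normalised on ingest (T -> U) and never produced on output.
"""

from __future__ import annotations

from itertools import product

RNA_BASES = "ACGU"

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: All 64 trinucleotides in lexicographic (A<C<G<U) order.
ALL_TRIPLETS: tuple[str, ...] = tuple(
    "".join(p) for p in product(RNA_BASES, repeat=3)
)

TRIPLET_INDEX: dict[str, int] = {t: i for i, t in enumerate(ALL_TRIPLETS)}


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U. Other letters pass through unchanged."""
    return seq.upper().replace("T", "U")


def is_rna(seq: str) -> bool:
    return all(b in RNA_BASES for b in seq)


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_count(seq: str) -> int:
    return sum(b in "GC" for b in seq)
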