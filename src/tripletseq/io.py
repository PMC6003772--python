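"""File formats and run metadata.

Reads are held in memory as lightweight ``Read`` tuples (id, sequence);
FASTQ is the on-disk interchange format (4-line records, constant 'I'
qualities on output).  Sequences are RNA internally: T is accepted on input
and normalised to U, U is always emitted on output.
"""

from __future__ import annotations

import hashlib
import json
import sys
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .nucleic import normalize_rna


class Read(NamedTuple):
    id: str
    seq: str


def read_fastq(path) -> list[Read]:
    """Parse a 4-line FASTQ file into Reads, normalising T -> U.

    Raises ``ValueError`` naming the (0-based) record index of the first
    malformed or truncated record.
    """
    reads: list[Read] = []
    it = SeqIO.parse(path, "fastq")
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return reads
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record at index {len(reads)} in {path}: {exc}"
            ) from exc
        reads.append(Read(rec.id, normalize_rna(str(rec.seq))))


def write_fastq(reads: Iterable[Read], path) -> int:
    """Write reads as FASTQ with constant 'I' quality; returns record count."""

    def records():
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(r.seq)
            yield rec

    return SeqIO.write(records(), str(path), "fastq")


def sequences(reads: Iterable[Read | str]) -> Iterable[str]:
    """Yield plain sequence strings from Reads or strings interchangeably."""
    for r in reads:
        yield r if isinstance(r, str) else r.seq


# --------------------------------------------------------------- run metadata

def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_metadata(config: dict) -> dict:
    return {
        "tool": "tripletseq",
        "version": __version__,
        "config": config,
        "config_hash": config_hash(config),
    }


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False)
        fh.write("\n")


def log_tallies(name: str, tallies: dict, sidecar_path=None) -> None:
    """Log discard tallies to stderr and optionally to a sidecar JSON."""
    total = sum(tallies.values())
    print(f"[tripletseq] {name}: {total} reads discarded "
          f"({', '.join(f'{k}={v}' for k, v in sorted(tallies.items())) or 'none'})",
          file=sys.stderr)
    if sidecar_path is not None:
        write_json({"stage": name, "discards": dict(tallies)}, sidecar_path)
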