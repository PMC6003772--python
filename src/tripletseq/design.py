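"""Assay design: templates, primer variants and the balanced 12-template set.

The fidelity assay extends a primer across a template that encodes the
product CCC-XXX-CCC, where XXX (the *cognate* product triplet) varies over
12 trinucleotides chosen so that every base occurs exactly three times at
every triplet position.  Each template is paired with a distinct 4-nt
primer-variant tag that identifies it after sequencing.  One special case:
when the cognate is ACC the downstream context is UCC rather than CCC, so
the encoded product avoids a terminal run of G on the template strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .nucleic import RNA_BASES, is_rna, normalize_rna, revcomp

DEFAULT_PRIMER_CORE = "ACGAGUAGUCGA"
DEFAULT_ADAPTOR = "GAUCGGAAGAGCACACGUCU"

UPSTREAM_CONTEXT = "CCC"


@dataclass(frozen=True)
class TemplateSpec:
    """One primer/template pair of the fidelity assay."""

    id: str
    template: str          # template trinucleotide N'N'N', 5'->3'
    cognate: str           # encoded product triplet (revcomp of template)
    upstream: str          # product context before the variable triplet
    downstream: str        # product context after it (CCC, or UCC for ACC)
    primer_variant: str    # 4-nt demultiplexing tag

    def __post_init__(self) -> None:
        if revcomp(self.template) != self.cognate:
            raise ValueError(
                f"template {self.template!r}: cognate {self.cognate!r} is not "
                f"its reverse complement"
            )
        for name in ("template", "cognate", "upstream", "downstream"):
            if not is_rna(getattr(self, name)):
                raise ValueError(f"{name} is not pure RNA: {getattr(self, name)!r}")

    @property
    def control_substrates(self) -> frozenset[str]:
        """Triplets present in this template's positive-control reaction.

        The control contains only the cognate and the downstream-context
        substrate(s): CCC, plus UCC for the ACC-cognate template.
        """
        return frozenset({self.cognate, "CCC"} | {self.downstream})


@dataclass
class AssayDesign:
    """The full multiplexed assay: templates plus shared primer core and adaptor."""

    templates: list[TemplateSpec]
    primer_core: str = DEFAULT_PRIMER_CORE
    adaptor: str = DEFAULT_ADAPTOR

    def __post_init__(self) -> None:
        variants = [t.primer_variant for t in self.templates]
        if len(set(variants)) != len(variants):
            raise ValueError("primer-variant sequences must be pairwise distinct")
        lengths = {len(v) for v in variants}
        if len(lengths) > 1:
            raise ValueError("primer-variant tags must share one length")

    @property
    def template_ids(self) -> list[str]:
        return [t.id for t in self.templates]

    @property
    def variant_length(self) -> int:
        return len(self.templates[0].primer_variant)

    @property
    def primer_length(self) -> int:
        return self.variant_length + len(self.primer_core)

    def template_by_id(self, tid: str) -> TemplateSpec:
        for t in self.templates:
            if t.id == tid:
                return t
        raise KeyError(tid)

    def primer_for(self, t: TemplateSpec) -> str:
        return t.primer_variant + self.primer_core

    def check_balance(self) -> None:
        """Raise unless each base occurs exactly 3x at each cognate position."""
        n = len(self.templates)
        if n != 12:
            raise ValueError(f"expected 12 templates, got {n}")
        for pos in range(3):
            counts = {b: 0 for b in RNA_BASES}
            for t in self.templates:
                counts[t.cognate[pos]] += 1
            if any(c != 3 for c in counts.values()):
                raise ValueError(f"position {pos + 1} base counts unbalanced: {counts}")

    # ------------------------------------------------------------------ YAML
    def to_dict(self) -> dict:
        return {
            "primer_core": self.primer_core,
            "adaptor": self.adaptor,
            "templates": [
                {
                    "id": t.id,
                    "template": t.template,
                    "cognate": t.cognate,
                    "upstream": t.upstream,
                    "downstream": t.downstream,
                    "primer_variant": t.primer_variant,
                }
                for t in self.templates
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssayDesign":
        templates = [
            TemplateSpec(
                id=str(t["id"]),
                template=normalize_rna(t["template"]),
                cognate=normalize_rna(t["cognate"]),
                upstream=normalize_rna(t.get("upstream", UPSTREAM_CONTEXT)),
                downstream=normalize_rna(t["downstream"]),
                primer_variant=normalize_rna(t["primer_variant"]),
            )
            for t in d["templates"]
        ]
        return cls(
            templates=templates,
            primer_core=normalize_rna(d.get("primer_core", DEFAULT_PRIMER_CORE)),
            adaptor=normalize_rna(d.get("adaptor", DEFAULT_ADAPTOR)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AssayDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _pick_variants(rng: np.random.Generator, n: int, length: int = 4) -> list[str]:
    # greedy pick of tags with pairwise Hamming distance >= 2, so a single
    # sequencing error cannot turn one tag into another
    from itertools import product as iproduct

    pool = ["".join(p) for p in iproduct(RNA_BASES, repeat=length)]
    order = rng.permutation(len(pool))
    chosen: list[str] = []
    for i in order:
        cand = pool[i]
        if all(_hamming(cand, c) >= 2 for c in chosen):
            chosen.append(cand)
            if len(chosen) == n:
                return chosen
    raise RuntimeError("could not select enough primer-variant tags")


def design_balanced_templates(seed: int = 0) -> AssayDesign:
    """Generate a compositionally balanced 12-template assay design.

    The 12 cognate product triplets are drawn so that each of A, C, G, U
    appears exactly three times at each of the three positions.  ACC is
    always included so the design exercises the UCC downstream-context rule.
    Deterministic for a fixed seed; different seeds may give different
    (equally balanced) sets.
    """
    rng = np.random.default_rng(seed)
    fixed = "ACC"
    # residual per-position base multisets after reserving ACC
    residual = []
    for pos in range(3):
        col = [b for b in RNA_BASES for _ in range(3)]
        col.remove(fixed[pos])
        residual.append(col)

    for _ in range(10_000):
        cols = [list(rng.permutation(residual[p])) for p in range(3)]
        cognates = [fixed] + ["".join(cols[p][i] for p in range(3)) for i in range(11)]
        if len(set(cognates)) == 12:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to generate a distinct balanced template set")

    variants = _pick_variants(rng, 12)
    templates = [
        TemplateSpec(
            id=f"T{i + 1:02d}",
            template=revcomp(cog),
            cognate=cog,
            upstream=UPSTREAM_CONTEXT,
            downstream="UCC" if cog == "ACC" else "CCC",
            primer_variant=variants[i],
        )
        for i, cog in enumerate(cognates)
    ]
    design = AssayDesign(templates=templates)
    design.check_balance()
    return design
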