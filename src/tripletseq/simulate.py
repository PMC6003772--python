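"""Synthetic-data generators with known ground truth.

Every input the analysis stages consume can be simulated here: fidelity-assay
reads (experimental and positive-control), long-segment reads, extension
ladders and dose-response curves.  All generators are deterministic given
their seed, so downstream parameter-recovery tests have exact ground truth.

Fidelity-assay reads follow the assay's product architecture::

    [4-nt primer-variant tag][primer core][CCC][1-3 incorporated triplets][adaptor]

The first incorporated triplet is drawn from the template's misincorporation
distribution; any further triplets copy the downstream context (CCC, or UCC
on the ACC-cognate template).  Per-base substitution noise emulates the
sequencing/amplification background that the control samples exist to
subtract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .design import AssayDesign
from .io import Read
from .nucleic import ALL_TRIPLETS, RNA_BASES, TRIPLET_INDEX

_BASE_ARR = np.frombuffer(b"ACGU", dtype=np.uint8)
_DEFAULT_ADDITIONS = (1.0 / 3, 1.0 / 3, 1.0 / 3)


@dataclass
class IncorporationModel:
    """Per-template incorporation probabilities plus read-level noise.

    Parameters
    ----------
    distributions
        Mapping template id -> probability vector over the 64 triplets
        (lexicographic A<C<G<U order), the chance that each triplet is the
        first one incorporated after the upstream CCC.
    additions
        Probabilities of adding 1, 2 or 3 triplets in total.
    seq_error_rate
        Per-base substitution probability applied uniformly along each read,
        modelling sequencing/amplification background (must be < 0.5).
    """

    distributions: dict[str, np.ndarray]
    additions: tuple[float, float, float] = _DEFAULT_ADDITIONS
    seq_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.seq_error_rate < 0.5:
            raise ValueError("seq_error_rate must lie in [0, 0.5)")
        adds = np.asarray(self.additions, dtype=float)
        if adds.shape != (3,) or adds.min() < 0 or abs(adds.sum() - 1) > 1e-9:
            raise ValueError("additions must be 3 probabilities summing to 1")
        for tid, p in self.distributions.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (64,):
                raise ValueError(f"{tid}: distribution must have 64 entries")
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"{tid}: probabilities must be >=0 and sum to 1")
            self.distributions[tid] = p

    # ------------------------------------------------------------ constructors
    @classmethod
    def perfect(cls, design: AssayDesign, **kw) -> "IncorporationModel":
        """Error-free incorporation: probability 1 on each cognate triplet."""
        dists = {}
        for t in design.templates:
            p = np.zeros(64)
            p[TRIPLET_INDEX[t.cognate]] = 1.0
            dists[t.id] = p
        return cls(dists, **kw)

    @classmethod
    def random_errors(
        cls,
        design: AssayDesign,
        seed: int,
        error_lo: float = 0.02,
        error_hi: float = 0.08,
        **kw,
    ) -> "IncorporationModel":
        """Random misincorporation profile with realistic structure.

        Each template misincorporates with total probability drawn uniformly
        from [error_lo, error_hi]; the error mass is spread over non-cognate
        triplets with weights decaying 10-fold per additional mismatch from
        the cognate, mimicking the dominance of single-base (e.g. wobble)
        errors.
        """
        rng = np.random.default_rng(seed)
        dists = {}
        for t in design.templates:
            e_total = rng.uniform(error_lo, error_hi)
            w = np.array([
                0.0 if trip == t.cognate
                else rng.gamma(2.0) * 10.0 ** -(sum(a != b for a, b in zip(trip, t.cognate)) - 1)
                for trip in ALL_TRIPLETS
            ])
            p = e_total * w / w.sum()
            p[TRIPLET_INDEX[t.cognate]] = 1.0 - e_total
            dists[t.id] = p
        return cls(dists, **kw)

    # ---------------------------------------------------------------- helpers
    def check_matches(self, design: AssayDesign) -> None:
        if set(self.distributions) != set(design.template_ids):
            raise ValueError(
                "model template ids do not match the design: "
                f"{sorted(self.distributions)} vs {sorted(design.template_ids)}"
            )

    def to_dict(self) -> dict:
        return {
            "additions": list(self.additions),
            "seq_error_rate": self.seq_error_rate,
            "distributions": {
                tid: {ALL_TRIPLETS[i]: float(p[i]) for i in np.nonzero(p)[0]}
                for tid, p in self.distributions.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IncorporationModel":
        dists = {}
        for tid, sparse in d["distributions"].items():
            p = np.zeros(64)
            for trip, prob in sparse.items():
                p[TRIPLET_INDEX[trip]] = float(prob)
            dists[tid] = p
        return cls(
            dists,
            additions=tuple(d.get("additions", _DEFAULT_ADDITIONS)),
            seq_error_rate=float(d.get("seq_error_rate", 0.0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "IncorporationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _apply_noise(seqs: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    """Independent per-base substitutions at `rate`, uniform over alternatives."""
    if rate <= 0:
        return seqs
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    n_err = rng.binomial(lengths, rate)
    out = list(seqs)
    for i in np.nonzero(n_err)[0]:
        s = list(out[i])
        pos = rng.choice(lengths[i], size=n_err[i], replace=False)
        for p in pos:
            alts = [b for b in RNA_BASES if b != s[p]]
            s[p] = alts[rng.integers(3)]
        out[i] = "".join(s)
    return out


def _assemble_reads(
    design: AssayDesign,
    first_triplets: list[str],
    template_idx: np.ndarray,
    n_additions: np.ndarray,
    noise: float,
    rng: np.random.Generator,
    prefix: str,
) -> list[Read]:
    seqs = []
    for i, (ti, trip, k) in enumerate(zip(template_idx, first_triplets, n_additions)):
        t = design.templates[ti]
        seqs.append(
            t.primer_variant + design.primer_core + t.upstream
            + trip + t.downstream * (k - 1) + design.adaptor
        )
    seqs = _apply_noise(seqs, noise, rng)
    return [Read(f"{prefix}{i:08d}", s) for i, s in enumerate(seqs)]


def gen_fidelity_reads(
    design: AssayDesign,
    model: IncorporationModel,
    n_reads: int,
    seed: int,
) -> list[Read]:
    """Simulate experimental fidelity-assay reads (all 64 substrates present).

    Templates are assigned uniformly at random, so reads arrive shuffled
    across templates as in a multiplexed sequencing run.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    model.check_matches(design)
    rng = np.random.default_rng(seed)
    template_idx = rng.integers(len(design.templates), size=n_reads)
    n_additions = rng.choice([1, 2, 3], size=n_reads, p=model.additions)
    # draw first incorporated triplets template by template for vectorised choice
    firsts = [""] * n_reads
    for ti, t in enumerate(design.templates):
        mask = np.nonzero(template_idx == ti)[0]
        if mask.size:
            draws = rng.choice(64, size=mask.size, p=model.distributions[t.id])
            for j, d in zip(mask, draws):
                firsts[j] = ALL_TRIPLETS[d]
    return _assemble_reads(
        design, firsts, template_idx, n_additions, model.seq_error_rate, rng, "exp"
    )


def gen_control_reads(
    design: AssayDesign,
    n_reads: int,
    control_error: float,
    seed: int,
    p_cognate: float = 0.95,
    additions: tuple[float, float, float] = _DEFAULT_ADDITIONS,
) -> list[Read]:
    """Simulate positive-control reads (cognate + downstream substrates only).

    Each template's control reaction contains only its own substrate set:
    cognate and CCC (plus UCC for the ACC-cognate template).  The first
    counted triplet is the cognate with probability `p_cognate`, otherwise
    one of the other control substrates; `control_error` is the per-base
    substitution noise whose footprint the background-correction step is
    designed to remove.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0.0 <= control_error < 0.5:
        raise ValueError("control_error must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    template_idx = rng.integers(len(design.templates), size=n_reads)
    n_additions = rng.choice([1, 2, 3], size=n_reads, p=additions)
    firsts = [""] * n_reads
    for ti, t in enumerate(design.templates):
        subs = sorted(t.control_substrates)
        others = [s for s in subs if s != t.cognate]
        probs = np.array(
            [p_cognate if s == t.cognate else (1 - p_cognate) / len(others)
             for s in subs]
        ) if others else np.array([1.0])
        mask = np.nonzero(template_idx == ti)[0]
        if mask.size:
            draws = rng.choice(len(subs), size=mask.size, p=probs / probs.sum())
            for j, d in zip(mask, draws):
                firsts[j] = subs[d]
    return _assemble_reads(
        design, firsts, template_idx, n_additions, control_error, rng, "ctl"
    )


def gen_segment_reads(
    reference: str,
    per_position_error: np.ndarray,
    n_reads: int,
    seed: int,
) -> list[Read]:
    """Full-length copies of `reference` with independent per-position errors.

    `per_position_error[p]` is the substitution probability at position p
    (uniform over the three alternative bases).
    """
    rates = np.asarray(per_position_error, dtype=float)
    if rates.shape != (len(reference),):
        raise ValueError(
            f"per_position_error length {rates.size} != reference length {len(reference)}"
        )
    if rates.min() < 0 or rates.max() >= 1:
        raise ValueError("error rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    base_idx = np.searchsorted(_BASE_ARR, ref)  # ACGU are sorted bytes
    mat = np.broadcast_to(base_idx, (n_reads, ref.size)).copy()
    hit = rng.random((n_reads, ref.size)) < rates
    shift = rng.integers(1, 4, size=hit.sum())
    mat[hit] = (mat[hit] + shift) % 4
    seqs = _BASE_ARR[mat].tobytes().decode()
    L = ref.size
    return [Read(f"seg{i:08d}", seqs[i * L:(i + 1) * L]) for i in range(n_reads)]


def gen_ladder(
    junction_extents: np.ndarray,
    n_molecules: float,
    noise: float,
    seed: int,
):
    """Simulate an extension-product intensity ladder from junction extents.

    A molecule passes junction j with probability `junction_extents[j-1]`;
    the expected intensity at length k is n_molecules times the probability
    of ligating through the first k junctions and stalling at the next.
    Multiplicative log-normal noise of scale `noise` is applied per band.
    """
    from .ladders import Ladder

    e = np.asarray(junction_extents, dtype=float)
    if e.size == 0 or e.min() < 0 or e.max() > 1:
        raise ValueError("extents must be a non-empty vector in [0, 1]")
    rng = np.random.default_rng(seed)
    surv = np.concatenate([[1.0], np.cumprod(e)])  # P(reach length k)
    frac = surv.copy()
    frac[:-1] *= 1.0 - e  # stall at junction k+1
    intensities = n_molecules * frac
    if noise > 0:
        intensities = intensities * np.exp(noise * rng.standard_normal(e.size + 1))
    return Ladder(intensities)


def gen_dose_response(
    fmax: float,
    K: float,
    n: float,
    concentrations: np.ndarray,
    noise_sd: float,
    seed: int,
):
    """Hill-model dose-response points with Gaussian noise, clipped to [0, 1]."""
    from .binding import DoseResponse, hill_curve

    if K <= 0 or n <= 0:
        raise ValueError("K and n must be positive")
    c = np.asarray(concentrations, dtype=float)
    if c.min() < 0:
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    y = hill_curve(c, fmax, K, n)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(c.size)
    return DoseResponse(c, np.clip(y, 0.0, 1.0))
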