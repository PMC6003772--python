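"""Misincorporation counting, background correction and fidelity statistics.

The analysis chain is::

    reads -> count_triplets -> TripletCountTable (experimental / control)
          -> background_correct -> TripletCountTable (corrected)
          -> collate_positional -> PositionalErrorProfile
          -> positional_fidelity -> FidelityResult

Counting records, per demultiplexed template, the first complete triplet
incorporated after the upstream CCC.  Background correction removes the
sequencing/amplification error footprint estimated from positive-control
samples: for each error triplet the control count is scaled by the ratio of
cognate counts, subtracted (clamped at zero), and the subtracted mass is
reallocated to the cognate so the per-template total is conserved.  The
per-position error profiles of the 12 templates are then collated by
linear averaging (each base is encoded three times at each position), and
fidelities are summarised as geometric means: over the four bases at each
position, then over the three positions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .design import AssayDesign
from .io import sequences
from .nucleic import ALL_TRIPLETS, RNA_BASES, TRIPLET_INDEX

SAMPLE_KINDS = ("experimental", "control", "corrected")
_BASE_IDX = {b: i for i, b in enumerate(RNA_BASES)}


# ---------------------------------------------------------------- count table

@dataclass
class TripletCountTable:
    """Per-template counts of first-incorporated triplets.

    `counts` maps template id -> length-64 vector (lexicographic triplet
    order).  Raw (experimental/control) tables hold integers; corrected
    tables may be fractional.  `discards` tallies unassigned reads by reason.
    """

    sample_kind: str
    counts: dict[str, np.ndarray]
    discards: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.sample_kind not in SAMPLE_KINDS:
            raise ValueError(f"sample_kind must be one of {SAMPLE_KINDS}")
        for tid, v in self.counts.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (64,) or v.min() < 0:
                raise ValueError(f"{tid}: counts must be 64 non-negative numbers")
            self.counts[tid] = v

    def get(self, template_id: str, triplet: str) -> float:
        return float(self.counts[template_id][TRIPLET_INDEX[triplet]])

    def total(self, template_id: str) -> float:
        return float(self.counts[template_id].sum())

    @property
    def grand_total(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    # ------------------------------------------------------------------- TSV
    def to_frame(self) -> pd.DataFrame:
        rows = [
            (tid, ALL_TRIPLETS[i], float(v[i]), self.sample_kind)
            for tid, v in sorted(self.counts.items())
            for i in np.nonzero(v)[0]
        ]
        return pd.DataFrame(rows, columns=["template_id", "triplet", "count", "sample_kind"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, template_ids=None) -> "TripletCountTable":
        kinds = df["sample_kind"].unique()
        if len(kinds) != 1:
            raise ValueError(f"table mixes sample kinds: {kinds}")
        ids = list(template_ids) if template_ids is not None else sorted(df["template_id"].unique())
        counts = {tid: np.zeros(64) for tid in ids}
        for tid, trip, cnt in zip(df["template_id"], df["triplet"], df["count"]):
            counts[str(tid)][TRIPLET_INDEX[trip]] += float(cnt)
        return cls(sample_kind=str(kinds[0]), counts=counts)

    @classmethod
    def from_tsv(cls, path, template_ids=None) -> "TripletCountTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"), template_ids)


# ------------------------------------------------------------- classification

@dataclass(frozen=True)
class ReadCall:
    """Outcome of classifying one read: a template assignment or a reason."""

    template_id: str | None
    triplets: tuple[str, ...] = ()
    reason: str | None = None

    @property
    def assigned(self) -> bool:
        return self.template_id is not None


def _match_primer(seq: str, design: AssayDesign, max_mismatch: int) -> tuple[str | None, str | None]:
    """Return (template_id, reason); exactly one of the two is None."""
    plen = design.primer_length
    head = seq[:plen]
    hits = []
    for t in design.templates:
        primer = design.primer_for(t)
        mm = sum(a != b for a, b in zip(head, primer))
        if mm <= max_mismatch:
            hits.append(t.id)
            if len(hits) > 1:
                return None, "ambiguous_primer"
    if not hits:
        return None, "no_primer_match"
    return hits[0], None


def classify_read(read, design: AssayDesign, max_mismatch: int = 0) -> ReadCall:
    """Demultiplex one read and extract its incorporated triplets.

    The read must start with a primer variant + shared core (within
    `max_mismatch` substitutions over the whole primer; two templates within
    tolerance is an ambiguity), followed by the upstream CCC.  The remainder
    up to the adaptor is split into 3-nt frames; a trailing partial frame is
    dropped.  Reads with 0 or more than 3 complete triplets are gated out.
    """
    seq = read if isinstance(read, str) else read.seq
    plen = design.primer_length
    if len(seq) < plen + 3:
        return ReadCall(None, reason="too_short")

    tid, reason = _match_primer(seq, design, max_mismatch)
    if tid is None:
        return ReadCall(None, reason=reason)
    t = design.template_by_id(tid)

    ext = seq[plen:]
    if not ext.startswith(t.upstream):
        return ReadCall(None, reason="no_ccc_start")
    rest = ext[len(t.upstream):]

    rest = _trim_adaptor(rest, design.adaptor)
    n_full = len(rest) // 3
    if n_full == 0:
        return ReadCall(None, reason="frame_incomplete")
    if n_full > 3:
        return ReadCall(None, reason="too_many_triplets")
    triplets = tuple(rest[i * 3:(i + 1) * 3] for i in range(n_full))
    if any(b not in RNA_BASES for b in triplets[0]):
        return ReadCall(None, reason="non_acgu")
    return ReadCall(tid, triplets=triplets)


def _trim_adaptor(rest: str, adaptor: str, seed_len: int = 8, seed_mm: int = 1) -> str:
    """Cut `rest` at the first adaptor occurrence (seed match, <=1 mismatch)."""
    seed = adaptor[:seed_len]
    pos = rest.find(seed)
    if pos >= 0:
        return rest[:pos]
    k = len(seed)
    for p in range(len(rest) - k + 1):
        window = rest[p:p + k]
        mm = 0
        for a, b in zip(window, seed):
            if a != b:
                mm += 1
                if mm > seed_mm:
                    break
        else:
            return rest[:p]
    return rest


def count_triplets(
    reads,
    design: AssayDesign,
    max_mismatch: int = 0,
    sample_kind: str = "experimental",
) -> TripletCountTable:
    """Tally the first post-CCC triplet of every assignable read.

    Unassigned reads are tallied by reason; assigned counts plus discards
    always equal the number of input reads.
    """
    counts = {t.id: np.zeros(64) for t in design.templates}
    discards: Counter = Counter()
    for seq in sequences(reads):
        call = classify_read(seq, design, max_mismatch)
        if call.assigned:
            counts[call.template_id][TRIPLET_INDEX[call.triplets[0]]] += 1
        else:
            discards[call.reason] += 1
    return TripletCountTable(sample_kind=sample_kind, counts=counts, discards=discards)


# --------------------------------------------------------- background correct

def background_correct(
    exp_table: TripletCountTable,
    ctrl_table: TripletCountTable,
    design: AssayDesign,
) -> TripletCountTable:
    """Subtract the positive-control error footprint from experimental counts.

    For each template with cognate counts C_x (experimental) and C_p
    (control), every error triplet's count E_x is reduced by
    min(E_x, E_p * C_x / C_p) and the subtracted mass is reallocated to the
    corrected cognate count, so per-template totals are conserved.  Triplets
    in the control substrate set (CCC, and UCC on the ACC-cognate template)
    are left uncorrected.
    """
    if set(exp_table.counts) != set(ctrl_table.counts):
        raise ValueError("experimental and control tables cover different templates")
    if set(exp_table.counts) != set(design.template_ids):
        raise ValueError("tables do not match the design's template ids")

    corrected: dict[str, np.ndarray] = {}
    for t in design.templates:
        ex = exp_table.counts[t.id].astype(float).copy()
        ep = ctrl_table.counts[t.id]
        ci = TRIPLET_INDEX[t.cognate]
        c_x, c_p = ex[ci], ep[ci]
        if c_p <= 0:
            raise ValueError(f"template {t.id}: control cognate count is zero")
        scale = c_x / c_p
        keep = np.zeros(64, dtype=bool)
        for s in t.control_substrates:
            keep[TRIPLET_INDEX[s]] = True
        sub = np.minimum(ex, ep * scale)
        sub[keep] = 0.0  # cognate and context substrates stay uncorrected
        ex -= sub
        ex[ci] = c_x + sub.sum()
        corrected[t.id] = ex
    return TripletCountTable(sample_kind="corrected", counts=corrected,
                             discards=Counter(exp_table.discards))


# -------------------------------------------------------------- collation

@dataclass
class PositionalErrorProfile:
    """Collated incorporation rates: position x encoded base x incorporated base.

    `rates[p, e, i]` is the frequency with which product base RNA_BASES[i]
    is incorporated at triplet position p+1 (5'->3') when RNA_BASES[e] is
    encoded there; each (position, encoded) row sums to 1.
    """

    rates: np.ndarray  # shape (3, 4, 4)
    total_count: float = 0.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (3, 4, 4):
            raise ValueError("rates must have shape (3, 4, 4)")
        sums = self.rates.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each (position, encoded base) row must sum to 1")

    @classmethod
    def identity(cls) -> "PositionalErrorProfile":
        return cls(np.broadcast_to(np.eye(4), (3, 4, 4)).copy())

    @property
    def diagonal(self) -> np.ndarray:
        """Cognate-base incorporation fraction, shape (3, 4)."""
        return np.einsum("pii->pi", self.rates)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p + 1, RNA_BASES[e], RNA_BASES[i], float(self.rates[p, e, i]))
            for p in range(3) for e in range(4) for i in range(4)
        ]
        return pd.DataFrame(rows, columns=["position", "encoded", "incorporated", "rate"])


def collate_positional(
    corrected: TripletCountTable,
    design: AssayDesign,
) -> PositionalErrorProfile:
    """Collate per-template marginals into the position x base error profile.

    For each template, corrected counts give the marginal incorporated-base
    frequency at each triplet position; each (position, encoded-base) cell is
    then the unweighted arithmetic mean over the three templates whose
    cognate carries that base at that position.
    """
    if set(corrected.counts) != set(design.template_ids):
        raise ValueError("count table does not cover the design's templates")
    # marginal base composition of each triplet position, per template
    base_at = np.zeros((3, 64, 4))
    for i, trip in enumerate(ALL_TRIPLETS):
        for p in range(3):
            base_at[p, i, _BASE_IDX[trip[p]]] = 1.0

    cells: list[list[list[np.ndarray]]] = [[[] for _ in range(4)] for _ in range(3)]
    for t in design.templates:
        v = corrected.counts[t.id]
        tot = v.sum()
        if tot <= 0:
            raise ValueError(f"template {t.id}: no counts to collate")
        for p in range(3):
            marg = base_at[p].T @ v / tot
            cells[p][_BASE_IDX[t.cognate[p]]].append(marg)

    rates = np.zeros((3, 4, 4))
    for p in range(3):
        for e in range(4):
            if not cells[p][e]:
                raise ValueError(
                    f"no template encodes {RNA_BASES[e]} at position {p + 1}; "
                    "design is not balanced"
                )
            rates[p, e] = np.mean(cells[p][e], axis=0)
    return PositionalErrorProfile(rates, total_count=corrected.grand_total)


# ---------------------------------------------------------- fidelity summary

@dataclass
class FidelityResult:
    """Geometric-mean fidelity summary, all values in percent."""

    per_base_pct: np.ndarray   # shape (3, 4): position x encoded base
    positional_pct: np.ndarray  # shape (3,)
    overall_pct: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_base_pct": {
                f"position_{p + 1}": {RNA_BASES[b]: float(self.per_base_pct[p, b])
                                      for b in range(4)}
                for p in range(3)
            },
            "positional_pct": [float(x) for x in self.positional_pct],
            "overall_pct": float(self.overall_pct),
            "metadata": self.metadata,
        }


def positional_fidelity(
    profile: PositionalErrorProfile,
    floor: float | None = None,
) -> FidelityResult:
    """Summarise a profile as geometric-mean fidelities.

    Per-base fidelity is the diagonal (cognate-incorporation) rate; the
    positional fidelity is the geometric mean over the four encoded bases
    and the overall fidelity the geometric mean over the three positions.
    Zero diagonal entries are floored (default 1 / (total count + 1)) before
    taking logs.
    """
    if floor is None:
        floor = 1.0 / (profile.total_count + 1.0) if profile.total_count > 0 else 1e-9
    diag = np.maximum(profile.diagonal, floor)
    positional = gmean(diag, axis=1)
    overall = float(gmean(positional))
    return FidelityResult(
        per_base_pct=100.0 * diag,
        positional_pct=100.0 * positional,
        overall_pct=100.0 * overall,
        metadata={"zero_floor": floor, "total_count": profile.total_count},
    )


# ------------------------------------------------------------ pair contests

def contest_ratio(
    table: TripletCountTable,
    template_id: str,
    cognate: str,
    mispair: str,
) -> float:
    """Mispair incorporation fraction mispair / (mispair + cognate)."""
    m = table.get(template_id, mispair)
    c = table.get(template_id, cognate)
    if m + c == 0:
        raise ValueError(
            f"template {template_id}: no counts for {cognate} or {mispair}"
        )
    return m / (m + c)


def proportional_reduction(
    table_before: TripletCountTable,
    table_after: TripletCountTable,
    template_id: str,
    cognate: str,
    mispair: str,
) -> float:
    """Proportional drop in the mispair fraction between two conditions.

    Returns 1 - ratio_after / ratio_before, e.g. 0.61 for a 61% reduction
    in relative mispair incorporation.
    """
    r1 = contest_ratio(table_before, template_id, cognate, mispair)
    r2 = contest_ratio(table_after, template_id, cognate, mispair)
    if r1 == 0:
        raise ValueError("baseline mispair ratio is zero; reduction undefined")
    return 1.0 - r2 / r1
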