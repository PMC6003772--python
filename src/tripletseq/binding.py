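"""Substrate-level binding models: cooperative invasion and pool dimerization.

Two quantitative models of triplet-substrate behaviour:

* **Hill dose-response fitting** for the steep, sigmoidal dependence of
  primer extension on triplet concentration seen when triplets must
  cooperatively invade (unfold) structured templates.  The Hill form
  ``y = fmax * c^n / (K^n + c^n)`` is phenomenological; an all-or-none
  m-triplet invasion mechanism is its n = m special case.

* **Triplet:anti-triplet dimerization equilibria** in substrate pools.
  Every triplet has exactly one perfect reverse-complement partner (no
  3-mer is self-complementary), so a 64-triplet pool partitions into 32
  independent two-species equilibria.  Duplex stability is modelled with a
  minimal 3-bp free-energy scheme (per-GC-pair and per-AU-pair increments
  plus an initiation penalty); stronger-pairing GC-rich triplets dimerise
  more and so have their free concentrations selectively buffered, which
  predicts reduced misincorporation of GC-rich mispairing triplets once
  complementary triplets are present.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares

from .nucleic import ALL_TRIPLETS, gc_count, revcomp

R_KCAL = 1.987204259e-3  # gas constant, kcal / (mol K)


# ------------------------------------------------------------- dose response

@dataclass
class DoseResponse:
    """Concentration / extension-fraction points."""

    concentration: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration.shape != self.response.shape:
            raise ValueError("concentration and response must have equal length")
        if self.concentration.min() < 0:
            raise ValueError("concentrations must be non-negative")

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "concentration": self.concentration,
            "response": self.response,
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DoseResponse":
        df = pd.read_csv(path, sep="\t")
        return cls(df["concentration"].to_numpy(), df["response"].to_numpy())


def hill_curve(c, fmax: float, K: float, n: float):
    """Hill saturation curve, safe at c = 0 for any n > 0."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        # work via (c/K)^n to avoid overflow at large c and n
        r = np.where(c > 0, (c / K) ** n, 0.0)
    return fmax * r / (1.0 + r)


@dataclass
class HillFit:
    fmax: float
    K: float
    n: float
    rss: float
    start_diagnostics: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.fmax <= 1.2 and self.K > 0 and self.n > 0):
            raise ValueError(
                f"fit outside admissible range: fmax={self.fmax}, K={self.K}, n={self.n}"
            )

    def to_dict(self) -> dict:
        return {"fmax": self.fmax, "K": self.K, "n": self.n, "rss": self.rss}


def hill_fit(points: DoseResponse) -> HillFit:
    """Least-squares Hill fit with a deterministic multi-start grid.

    Starts combine n in {0.5, 1, 2, 4, 8} with K at the quartiles of the
    positive concentrations; the best converged start (lowest residual sum
    of squares) wins.  Requires at least 4 points spanning a >= 4-fold
    concentration range.
    """
    c, y = points.concentration, points.response
    pos = c[c > 0]
    if c.size < 4:
        raise ValueError("need at least 4 dose-response points")
    if pos.size == 0 or pos.max() / pos.min() < 4:
        raise ValueError("concentrations must span at least a 4-fold range")

    def resid(theta):
        return hill_curve(c, *theta) - y

    fmax0 = float(np.clip(y.max(), 0.05, 1.2))
    k_starts = np.quantile(pos, [0.25, 0.5, 0.75])
    bounds = ([1e-6, 1e-9, 1e-3], [1.2, 1e9, 50.0])

    best = None
    diagnostics = []
    for n0 in (0.5, 1.0, 2.0, 4.0, 8.0):
        for k0 in k_starts:
            x0 = [fmax0, float(k0), n0]
            try:
                sol = least_squares(resid, x0, bounds=bounds, method="trf")
            except Exception as exc:  # pragma: no cover - scipy failure path
                diagnostics.append({"start": x0, "error": str(exc)})
                continue
            rss = float(2 * sol.cost)
            diagnostics.append({"start": x0, "rss": rss, "success": bool(sol.success)})
            if sol.success and (best is None or rss < best[1]):
                best = (sol.x, rss)
    if best is None:
        raise RuntimeError(f"Hill fit failed from every start: {diagnostics}")
    x, rss = best
    return HillFit(fmax=float(x[0]), K=float(x[1]), n=float(x[2]), rss=rss,
                   start_diagnostics=diagnostics)


# ------------------------------------------------- dimerization equilibria

def pair_free_concentration(
    total_a: float, total_b: float, kd: float
) -> tuple[float, float, float]:
    """Free concentrations and dimer for one A + B <-> AB equilibrium.

    Solves free_a * free_b = kd * dimer with mass balance, via the stable
    root of the quadratic; units follow the inputs (kd in the same units).
    """
    if total_a < 0 or total_b < 0:
        raise ValueError("totals must be non-negative")
    if kd <= 0:
        raise ValueError("kd must be positive")
    s = total_a + total_b + kd
    disc = s * s - 4.0 * total_a * total_b
    dimer = 2.0 * total_a * total_b / (s + math.sqrt(disc))
    return total_a - dimer, total_b - dimer, dimer


@dataclass
class AffinityModel:
    """Minimal 3-bp duplex stability model for triplet:anti-triplet pairs.

    dG = g_init + n_GC * g_gc + n_AU * g_au (kcal/mol) over the three
    Watson-Crick pairs of the duplex; Kd = exp(dG / RT) in molar, reported
    in uM.  Defaults are illustrative round numbers for a cold (eutectic,
    266 K) regime, not fitted values.
    """

    g_gc: float = -2.0    # kcal/mol per G:C pair
    g_au: float = -0.5    # kcal/mol per A:U pair
    g_init: float = 3.5   # duplex initiation penalty, kcal/mol
    temperature: float = 266.0  # K

    def dg(self, triplet: str) -> float:
        n_gc = gc_count(triplet)
        return self.g_init + n_gc * self.g_gc + (3 - n_gc) * self.g_au

    def kd_um(self, triplet: str) -> float:
        """Dissociation constant of triplet : revcomp(triplet), in uM."""
        return 1e6 * math.exp(self.dg(triplet) / (R_KCAL * self.temperature))


@dataclass
class PoolSpec:
    """Total concentrations (uM) of the 64 triplets plus an affinity model."""

    totals: dict[str, float]
    affinity: AffinityModel = field(default_factory=AffinityModel)

    def __post_init__(self) -> None:
        unknown = set(self.totals) - set(ALL_TRIPLETS)
        if unknown:
            raise ValueError(f"not trinucleotides: {sorted(unknown)}")
        if any(v < 0 for v in self.totals.values()):
            raise ValueError("totals must be non-negative")
        # absent triplets are at concentration 0
        self.totals = {t: float(self.totals.get(t, 0.0)) for t in ALL_TRIPLETS}

    @classmethod
    def equimolar(cls, concentration_um: float, affinity: AffinityModel | None = None) -> "PoolSpec":
        """The all-64-triplet pool at `concentration_um` each."""
        return cls(
            totals={t: concentration_um for t in ALL_TRIPLETS},
            affinity=affinity or AffinityModel(),
        )

    def to_dict(self) -> dict:
        return {
            "totals": {t: v for t, v in self.totals.items() if v > 0},
            "affinity": {
                "g_gc": self.affinity.g_gc, "g_au": self.affinity.g_au,
                "g_init": self.affinity.g_init,
                "temperature": self.affinity.temperature,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PoolSpec":
        return cls(
            totals={k: float(v) for k, v in d["totals"].items()},
            affinity=AffinityModel(**d.get("affinity", {})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PoolSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class FreeConcentrations:
    """Equilibrium outcome per triplet: free and dimer-bound concentration."""

    free: dict[str, float]
    dimer: dict[str, float]
    totals: dict[str, float]

    def free_fraction(self, triplet: str) -> float:
        tot = self.totals[triplet]
        return self.free[triplet] / tot if tot > 0 else 1.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, gc_count(t), self.totals[t], self.free[t], self.dimer[t],
             self.free_fraction(t))
            for t in ALL_TRIPLETS
        ]
        df = pd.DataFrame(rows, columns=[
            "triplet", "gc_count", "total_um", "free_um", "dimer_um", "free_fraction",
        ])
        return df.sort_values(["gc_count", "triplet"]).reset_index(drop=True)


def pool_free_concentrations(pool: PoolSpec) -> FreeConcentrations:
    """Solve the 32 independent triplet:anti-triplet equilibria of a pool.

    Each triplet pairs only with its perfect reverse complement, so the
    pool decouples into 32 two-species mass-action problems solved in
    closed form.
    """
    free: dict[str, float] = {}
    dimer: dict[str, float] = {}
    done = set()
    for t in ALL_TRIPLETS:
        if t in done:
            continue
        partner = revcomp(t)
        kd = pool.affinity.kd_um(t)
        fa, fb, d = pair_free_concentration(pool.totals[t], pool.totals[partner], kd)
        free[t], free[partner] = fa, fb
        dimer[t] = dimer[partner] = d
        done.update((t, partner))
    return FreeConcentrations(free=free, dimer=dimer, totals=dict(pool.totals))


def predicted_error_modulation(
    free: FreeConcentrations,
    baseline_free: FreeConcentrations,
    cognate: str,
    mispair: str,
) -> float:
    """Predicted proportional change in the mispair:cognate error ratio.

    Under competitive incorporation the error odds scale with the ratio of
    free mispair to free cognate concentration; the return value is
    1 - odds(condition) / odds(baseline), i.e. positive when the condition
    (e.g. adding complementary triplets) is predicted to suppress the error.
    """
    for fc in (free, baseline_free):
        if fc.free[cognate] <= 0:
            raise ValueError(f"free cognate {cognate} concentration is zero")
    odds = free.free[mispair] / free.free[cognate]
    odds0 = baseline_free.free[mispair] / baseline_free.free[cognate]
    if odds0 == 0:
        warnings.warn("baseline error odds are zero; modulation undefined")
        return float("nan")
    return 1.0 - odds / odds0
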