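# tripletseq

Analysis toolkit for **triplet-based RNA synthesis by polymerase ribozymes**
— for researchers studying RNA-catalysed RNA replication who need to turn
deep-sequencing reads, gel ladders and dose-response measurements into
fidelity and substrate-pool statistics.

A triplet polymerase ribozyme extends a primer on an RNA template using
trinucleotide-triphosphate (`pppNNN`, "triplet") substrates. Quantifying how
*accurately* it does so, and why, involves several linked analyses that this
package implements as a tested, reusable library:

1. **Deep-sequencing fidelity profiling.** In the multiplexed assay, 12
   templates each encode a product `CCC-XXX-CCC`, where the 12 variable
   cognate triplets XXX are balanced so every base is encoded three times at
   each triplet position. Reads are demultiplexed by a primer-variant tag,
   gated to extensions of CCC plus 1–3 complete triplets, and the first
   triplet incorporated after CCC is counted. Background errors (sequencing,
   amplification) are estimated from positive-control reactions containing
   only each template's own substrates and subtracted per error triplet E:

   `E_r = E_x − E_p · (C_x / C_p)`  (clamped at 0; the subtracted mass is
   reallocated to the corrected cognate count `C_r`, conserving totals; the
   context substrates CCC — and UCC on the ACC template — stay uncorrected),

   where C is the cognate count and subscripts x/p denote the experimental
   and positive-control samples. Corrected counts are collated across the 12
   templates by linear averaging into a position × encoded-base error
   profile, and summarised as geometric means: per-base fidelities → a
   positional fidelity per triplet position → one overall fidelity.

2. **Segment-sequence fidelity.** For long synthesised segments sequenced
   against a known reference, reads with more than 9 mutations are excluded
   as unrelated products, per-position base fidelities are tabulated, and
   synthesis accuracy is summarised as the geometric mean over *internal*
   triplet positions (excluding the primer and the error-hot-spot final
   triplet).

3. **Ligation-extent statistics.** An extension-product ladder (one band
   intensity per number of substrates added) is converted to per-junction
   extents of ligation via survival ratios
   `e_j = Σ_{k≥j} I_k / Σ_{k≥j−1} I_k`, whose product telescopes exactly to
   the full-length yield `I_N / ΣI`.

4. **Cooperative substrate invasion.** Extension on structured templates
   turns on sigmoidally with triplet concentration; `hill_fit` fits
   `y = fmax·c^n / (K^n + c^n)` with a deterministic multi-start grid.

5. **Triplet-pool dimerization equilibria.** Each triplet has exactly one
   perfect reverse-complement partner, so an `pppNNN` pool decouples into 32
   mass-action dimerization equilibria solved in closed form, with duplex
   Kd from a minimal 3-bp free-energy model. GC-rich triplets dimerise more
   strongly, selectively buffering their free concentrations — which
   predicts the direction of misincorporation changes when complementary
   triplets are added.

A first-class **synthetic-data module** generates every input — balanced
assay designs, experimental and control FASTQ reads with configurable 64-way
misincorporation structure and per-base noise, segment reads, ladders and
dose-response tables — with known ground truth, so the whole pipeline is
testable end to end without any external data.

## Worked example

```bash
python examples/fidelity_pipeline.py
```

simulates 120,000 reads over the 12-template assay with a known
misincorporation profile plus 0.5% per-base background noise, matched
controls, and prints:

```
positional fidelities (%), positions 1-3 (5'->3'):
  truth       : [98.13 98.08 98.12]
  uncorrected : [97.68 97.63 97.58]
  corrected   : [98.12 98.13 98.1 ]
overall fidelity: truth 98.11%, uncorrected 97.63%, corrected 98.11%
```

The uncorrected estimate is biased ~0.5 percentage points low by background
noise; background correction recovers the ribozyme's true positional
fidelities to within sampling error. The other examples
(`segment_fidelity.py`, `ligation_ladder.py`, `hill_fit.py`,
`pool_equilibrium.py`) each run one capability on a small input and explain
the numbers they print; the bundled measured segment dataset, for instance,
gives internal-triplet averages of 98.78% (defined triplets), 96.66%
(random pool) and 98.56% (low-G random pool).

A thin CLI mirrors the library for shell pipelines
(`tripletseq simulate-design / simulate-reads / count / correct / fidelity /
segment-fidelity / ladder / hill-fit / pool-eq / report`); see
`tripletseq --help`.

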