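# Methods

This note records the models implemented in `tripletseq`, their assumptions,
the defaults that matter, and the design choices made where the underlying
procedures left the details open.

## Fidelity assay model

**Read architecture.** An assay read is
`[4-nt primer-variant tag][shared primer core][CCC][1–3 incorporated
triplets][adaptor]`. Demultiplexing matches the full primer
(tag + core) at the read start within `max_mismatch` substitutions
(default 0, exact; a read within tolerance of two templates is discarded as
ambiguous). The extension must begin with the upstream context CCC; the
remainder up to the adaptor is split into 3-nt frames, a trailing partial
frame is dropped, and reads with 0 or more than 3 complete triplets are
gated out. Only the *first* post-CCC triplet is counted — subsequent
positions copy the downstream context (CCC, or UCC on the ACC-cognate
template, which avoids a terminal G-run on the template strand) and carry
no misincorporation information. Adaptor location uses an exact search for
the adaptor's first 8 nt with a ≤1-mismatch fallback scan, so a single
sequencing error in the adaptor seed does not shift the frame.

**Background correction.** Positive controls contain only each template's
own substrate set {cognate, CCC} (plus UCC for ACC). For each error triplet
the control count, scaled by the ratio of cognate counts `C_x / C_p`,
estimates the background contribution and is subtracted with a clamp at
zero; exactly the subtracted mass (not the nominal subtraction) is
reallocated to the corrected cognate, so per-template totals are conserved
to machine precision. Context substrates are never corrected — they are
legitimately present in both samples, so the subtraction logic does not
apply to them; their counts remain in the collated profile, a choice
recorded in the output metadata.

**Collation and summaries.** Position 1 is the 5' base of the incorporated
product triplet (it pairs with the 3' base of the template trinucleotide);
collation is keyed by encoded *product* base. Each (position, encoded base)
cell is the **unweighted** arithmetic mean over the three templates encoding
that base there — templates are not weighted by read depth, so a
deeply-sequenced template cannot dominate a cell. Fidelity summaries are
geometric means of fidelities (1 − error), first over the four encoded
bases at a position, then over the three positions; the alternative reading
(averaging errors rather than fidelities) differs only at second order for
the fidelity ranges involved. Zero diagonal entries are floored at
`1 / (total count + 1)` (configurable) before the log-space mean; real
profiles never reach zero, but simulated degenerate ones can.

## Segment fidelity

Reads are compared to the expected product by Hamming distance
(substitutions only): the products are fixed-length and the exclusion rule
is a mutation count, so gapped alignment is unnecessary; length-mismatched
reads are excluded under a separate tally rather than aligned. The default
exclusion threshold is >9 mutations (the >6 robustness variant is the same
operation with `max_mutations=6`). The internal-triplet average is the
geometric mean over all synthesised positions excluding only the final
triplet (the error hot-spot: the fidelity machinery needs a downstream
triplet to engage, so the last triplet is added with basal accuracy). On
the bundled measured dataset this rule reproduces the reported summaries
(98.78/96.66/98.56%) to rounding of the printed per-position inputs.

## Ladder statistics

The extent formula is not conventionalised for this assay; the survival
definition `e_j = tail(j) / tail(j−1)` was chosen because it is the unique
per-junction statistic that makes the mean extent and the full-length yield
mutually consistent: the product of extents telescopes *exactly* to
`I_N / ΣI` on every ladder. Junctions beyond the point where the ladder is
exhausted see a 0/0 ratio; they are reported as extent 0 with a warning
(no molecule arrived, none was ligated). Intensities are treated as
already-quantified densitometry values; image processing is out of scope.

## Dose-response fitting

The Hill form is phenomenological; a mechanistic all-or-none m-triplet
invasion model is its `n = m` special case and is not separately
implemented. The fit is ordinary least squares via `scipy`'s bounded
trust-region solver from a deterministic 15-point start grid
(n ∈ {0.5, 1, 2, 4, 8} × K at the quartiles of the positive
concentrations); the best converged start wins, which both avoids the
local-minimum sensitivity of single-start Hill fits and makes results
reproducible. Bounds: fmax ∈ (0, 1.2] (a fraction, with headroom for
normalisation error), K > 0, n ∈ (0, 50]. Inputs must have ≥4 points
spanning ≥4-fold in concentration — below that the three parameters are not
identifiable.

## Pool dimerization equilibria

The model is deliberately minimal: **perfect-complement pairs only**. Every
triplet has exactly one reverse-complement partner and no 3-mer is
self-complementary, so the 64-triplet pool decouples into 32 independent
two-species equilibria, each solved in closed form (stable quadratic root;
agreement with a bisection oracle to 1e-9). Near-cognate (mismatched) dimer
networks and nearest-neighbour sequence dependence are knowingly omitted —
the goal is the *direction* and *ordering* of buffering effects, not
absolute free concentrations. Duplex stability:
`ΔG = g_init + n_GC·g_GC + n_AU·g_AU`, `Kd = exp(ΔG/RT)`, with defaults
g_GC = −2.0, g_AU = −0.5, g_init = +3.5 kcal/mol at T = 266 K (the eutectic
ice-phase temperature of −7 °C). These are illustrative round numbers of
the right order for 3-bp RNA duplexes (Kd in the mM range), not fitted
values; all are overridable. Eutectic freeze-concentration (~4–5×) is not
modelled — concentrations are interpreted as operational. Error modulation
assumes error odds proportional to free-mispair / free-cognate
concentration; the predicted pair-contest reductions are validated for
sign and ordering only, since their measured magnitudes reflect kinetic and
network effects outside this equilibrium model.

## Synthetic data: what it does and does not emulate

The generator reproduces the assay's structure — balanced 12-template
design (ACC always included, exercising the UCC context rule), 4-nt
demultiplexing tags with pairwise Hamming distance ≥2, multinomial
64-triplet misincorporation per template, 1–3 triplet additions (uniform by
default, matching the gel-excision window of 2–4 total additions including
the first CCC), i.i.d. per-base substitution noise, and control reactions
whose first triplet is the cognate with probability 0.95. The default
random misincorporation profile draws a per-template error total uniformly
from 2–8% and spreads it over non-cognate triplets with 10-fold decay per
additional mismatch, mimicking the dominance of single-base (wobble-like)
errors at realistic overall fidelities (~97–98%).

Not modelled: PCR amplification bias, indels, quality scores (constant 'I'),
paired-end structure, template-assortment artefacts, and the off-target
priming contaminant class seen in real segment libraries. Passing tests
therefore demonstrate correct *analysis* of the assay's read structure and
noise model, not robustness to every artefact of a real sequencing run.
The actual template and primer-variant sequences used in the original
assay are not public; the generated designs are synthetic stand-ins that
satisfy the same composition constraints.

## Problem sizes and numerical choices

Recovery studies use 12 × 10⁵ clean reads for the headline
positional-fidelity recovery (binomial sampling error ≲0.05 pp per
position, comfortably inside the 0.3 pp acceptance band) and 20 replicates
of 12 × 5,000 reads for the correction-benefit comparison — at 0.5%
background noise the uncorrected bias (~0.5 pp) exceeds per-replicate
sampling noise (~0.1 pp) several-fold, so the comparison is well powered at
that depth. Hill recovery uses 100 seeded refits of 8-point curves at
σ = 0.02. All generators take one `numpy` Generator seeded per call;
identical inputs and seeds give byte-identical outputs, including FASTQ
files. Geometric means are computed in log space; corrected counts stay
real-valued (no re-rounding); count conservation and the ladder telescoping
identity are enforced to ~1e-9 relative in tests.

## Known limitations

Classification is exact-match oriented (default `max_mismatch=0`); highly
noisy real data would need a tolerant demultiplexer and quality filtering,
both out of scope. The pool equilibrium model's absolute free-fraction
changes at μM concentrations are small (mM-range Kd); conclusions drawn
from it are ordinal. The dose-response fitter assumes homoscedastic
Gaussian noise and does not propagate parameter uncertainty.
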