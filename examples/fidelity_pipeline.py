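"""Fidelity assay end to end: simulate reads, count, correct, summarise.

Simulates a multiplexed 12-template fidelity assay with a known
misincorporation profile plus 0.5% per-base background noise, matched
positive controls, and compares uncorrected vs background-corrected
geometric-mean fidelities against the known truth.
"""

import numpy as np

from tripletseq import (
    IncorporationModel,
    TripletCountTable,
    background_correct,
    collate_positional,
    count_triplets,
    design_balanced_templates,
    gen_control_reads,
    gen_fidelity_reads,
    positional_fidelity,
)

design = design_balanced_templates(seed=0)
model = IncorporationModel.random_errors(design, seed=11, seq_error_rate=0.005)

exp_reads = gen_fidelity_reads(design, model, n_reads=120_000, seed=1)
ctl_reads = gen_control_reads(design, n_reads=120_000, control_error=0.005, seed=2)

exp = count_triplets(exp_reads, design)
ctl = count_triplets(ctl_reads, design, sample_kind="control")
corrected = background_correct(exp, ctl, design)

truth_table = TripletCountTable(
    "corrected", {tid: p.copy() for tid, p in model.distributions.items()})
truth = positional_fidelity(collate_positional(truth_table, design))
raw = positional_fidelity(collate_positional(exp, design))
cor = positional_fidelity(collate_positional(corrected, design))

print("positional fidelities (%), positions 1-3 (5'->3'):")
print(f"  truth       : {np.round(truth.positional_pct, 2)}")
print(f"  uncorrected : {np.round(raw.positional_pct, 2)}")
print(f"  corrected   : {np.round(cor.positional_pct, 2)}")
print(f"overall fidelity: truth {truth.overall_pct:.2f}%, "
      f"uncorrected {raw.overall_pct:.2f}%, corrected {cor.overall_pct:.2f}%")
print("Background correction strips the sequencing-noise error footprint, "
      "pulling the estimate back toward the ribozyme's true fidelity.")
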