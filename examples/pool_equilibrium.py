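"""Triplet:anti-triplet dimerization buffers free substrate concentrations.

Solves the 32 independent complement-pair equilibria of the equimolar
64-triplet pool and shows (i) that GC-rich triplets keep a smaller free
fraction, and (ii) the predicted direction of the error-rate change when
complementary triplets are added to a cognate/mispair contest.
"""

from tripletseq import PoolSpec, pool_free_concentrations, predicted_error_modulation

pool = PoolSpec.equimolar(5.0)  # 5 uM each of the 64 triplets
free = pool_free_concentrations(pool)
df = free.to_frame()

print("mean free fraction by triplet GC content (equimolar 5 uM pool):")
print(df.groupby("gc_count")["free_fraction"].mean().to_string(float_format="%.6f"))

base = PoolSpec(totals={"ACC": 5.0, "GCC": 5.0})
cond = PoolSpec(totals={"ACC": 5.0, "GCC": 5.0, "GGU": 5.0, "GGC": 5.0})
red = predicted_error_modulation(
    pool_free_concentrations(cond), pool_free_concentrations(base),
    cognate="ACC", mispair="GCC")
print(f"\nACC (cognate) vs GCC (mispair) contest: adding both complements "
      f"changes the predicted error ratio by -{100 * red:.3f}%")
print("GC-rich triplets pair their anti-triplets more strongly, so adding "
      "complements selectively removes free mispairing GCC — the predicted "
      "error change is negative (fidelity improves), matching the observed "
      "direction in pair-contest experiments.")
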