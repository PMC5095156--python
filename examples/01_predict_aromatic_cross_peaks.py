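"""Predict the Tyr/Phe aromatic DQ-SQ cross peaks from observed SQ shifts.

The DQ sum rule places each bonded pair's cross peaks at F1 = delta_i +
delta_j; bonded near-equivalent carbons (the Phe ring envelope) collapse to
a single autocorrelation peak at twice their shift.
"""

from kerassign import load_observed_shifts, load_topologies, predict_dqsq

topologies = load_topologies()
text = load_observed_shifts("fig1_text")
shifts = {(r, a): float(s) for r, a, s in zip(text.residue, text.atom, text.shift_ppm)}

print("Tyr Ceps-Czeta pair (from SQ shifts 116 and 155 ppm):")
for p in predict_dqsq({"CE": shifts[("Y", "CE")], "CZ": shifts[("Y", "CZ")]},
                      topologies["Y"]):
    print(f"  F2 = {p.f2:6.1f} ppm   F1(DQ) = {p.f1:6.1f} ppm")

print("Tyr Cdelta-Ceps pair:")
for p in predict_dqsq({"CD": shifts[("Y", "CD")], "CE": shifts[("Y", "CE")]},
                      topologies["Y"]):
    print(f"  F2 = {p.f2:6.1f} ppm   F1(DQ) = {p.f1:6.1f} ppm")

print("Phe ring envelope (130 ppm) autocorrelation:")
for p in predict_dqsq({"CD": shifts[("F", "CD")], "CE": shifts[("F", "CE")]},
                      topologies["F"]):
    print(f"  F2 = {p.f2:6.1f} ppm   F1(DQ) = {p.f1:6.1f} ppm")

print("\nBoth members of a pair share the summed DQ coordinate; the 271/246/260")
print("ppm values are the resolved aromatic landmarks of the 2D spectrum.")
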