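"""Classify the observed fur shifts with the dCA - dCB chemical-shift index.

The index is invariant to the referencing convention (a constant offset
cancels in the difference), so solid-state shifts can be compared directly
against solution-derived reference values.
"""

from kerassign import classify, compute_index, load_observed_shifts
from kerassign.residue_model import csi_reference_table

refs = csi_reference_table()
obs = load_observed_shifts("table1")
shifts = {(r, a): float(s) for r, a, s in zip(obs.residue, obs.atom, obs.shift_ppm)}

print(f"{'residue':8} {'dCA':>6} {'dCB':>6} {'index':>6} {'class':>6} {'margin':>7}")
for residue in ("S", "P", "L", "R", "Y", "T", "V", "A", "K", "F", "I"):
    ca, cb = shifts[(residue, "CA")], shifts[(residue, "CB")]
    index = compute_index(ca, cb)
    cls, margin, _tie = classify(residue, index, refs)
    print(f"{residue:8} {ca:6.0f} {cb:6.0f} {index:6.0f} {cls:>6} {margin:7.2f}")

print("\nH = helix, S = sheet, C = coil; margin is the ppm gap to the")
print("second-nearest class reference (larger = more confident call).")
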