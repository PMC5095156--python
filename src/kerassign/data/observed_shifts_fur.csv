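# Observed 13C chemical shifts of uniformly labelled murine fur keratin (ppm, TSP
# scale, glycine CH2 at 43.1 ppm as secondary reference). Residue-type level
# assignments from 2D DQ-SQ and PDSD correlation data.
# provenance: table1 = printed assignment table; fig1_text = value quoted in the
# running discussion of the 2D spectrum (kept separately where the two disagree,
# e.g. Tyr CZ 156 vs 155; they are deliberately not reconciled).
# certainty: high = typeset bold (high degree of certainty); tentative = not bold,
# or flagged as not uniquely resolved (Arg, Lys) or as a tentative assignment
# (Ala CB).
residue,atom,shift_ppm,provenance,certainty
G,CO,172,table1,high
G,CA,43,table1,high
S,CA,59,table1,high
S,CB,67,table1,high
P,CA,60,table1,high
P,CB,30,table1,high
P,CG,25,table1,high
P,CD,48,table1,high
L,CO,175,table1,tentative
L,CA,55,table1,tentative
L,CB,40,table1,tentative
L,CG,24,table1,tentative
L,CD1,24,table1,tentative
L,CD2,24,table1,tentative
R,CA,55,table1,tentative
R,CB,25,table1,tentative
R,CG,25,table1,tentative
R,CD,40,table1,tentative
R,CZ,156,table1,tentative
Y,CO,174,table1,high
Y,CA,54,table1,high
Y,CB,36,table1,high
Y,CG,130,table1,high
Y,CD,130,table1,high
Y,CE,116,table1,high
Y,CZ,156,table1,high
Y,CD,130,fig1_text,high
Y,CE,116,fig1_text,high
Y,CZ,155,fig1_text,high
T,CO,175,table1,high
T,CA,63,table1,high
T,CB,65,table1,high
T,CG2,20,table1,high
V,CA,63,table1,high
V,CB,30,table1,high
V,CG1,19,table1,high
V,CG2,19,table1,high
A,CO,173,table1,tentative
A,CA,51,table1,tentative
A,CB,24,table1,tentative
K,CA,55,table1,tentative
K,CB,32,table1,tentative
K,CG,25,table1,tentative
K,CD,25,table1,tentative
K,CE,40,table1,tentative
F,CO,174,table1,high
F,CA,54,table1,high
F,CB,36,table1,high
F,CG,140,table1,high
F,CD,130,table1,high
F,CE,130,table1,high
F,CZ,137,table1,high
F,CG,137,fig1_text,high
F,CD,130,fig1_text,high
F,CE,130,fig1_text,high
I,CO,173,table1,tentative
I,CA,63,table1,high
I,CB,36,table1,high
I,CG1,26,table1,high
I,CG2,14,table1,high
I,CD1,12,table1,high
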