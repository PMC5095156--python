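# Carbon atoms of the 20 standard amino acids, collapsed equivalence convention:
# chemically near-equivalent aromatic ring positions (Phe/Tyr CD1/CD2, CE1/CE2) are
# represented by a single atom whose members are listed in equiv_members.
# quaternary = 1 marks non-protonated carbons whose cross peaks are weak under
# cross-polarization (aromatic quaternaries and the Arg guanidinium CZ); backbone
# C=O and side-chain carboxyl/amide carbons are not flagged because amide-Calpha
# correlations are strong in practice.
residue,atom,quaternary,equiv_members
G,CO,0,
G,CA,0,
A,CO,0,
A,CA,0,
A,CB,0,
S,CO,0,
S,CA,0,
S,CB,0,
C,CO,0,
C,CA,0,
C,CB,0,
T,CO,0,
T,CA,0,
T,CB,0,
T,CG2,0,
V,CO,0,
V,CA,0,
V,CB,0,
V,CG1,0,
V,CG2,0,
L,CO,0,
L,CA,0,
L,CB,0,
L,CG,0,
L,CD1,0,
L,CD2,0,
I,CO,0,
I,CA,0,
I,CB,0,
I,CG1,0,
I,CG2,0,
I,CD1,0,
P,CO,0,
P,CA,0,
P,CB,0,
P,CG,0,
P,CD,0,
M,CO,0,
M,CA,0,
M,CB,0,
M,CG,0,
M,CE,0,
D,CO,0,
D,CA,0,
D,CB,0,
D,CG,0,
N,CO,0,
N,CA,0,
N,CB,0,
N,CG,0,
E,CO,0,
E,CA,0,
E,CB,0,
E,CG,0,
E,CD,0,
Q,CO,0,
Q,CA,0,
Q,CB,0,
Q,CG,0,
Q,CD,0,
K,CO,0,
K,CA,0,
K,CB,0,
K,CG,0,
K,CD,0,
K,CE,0,
R,CO,0,
R,CA,0,
R,CB,0,
R,CG,0,
R,CD,0,
R,CZ,1,
H,CO,0,
H,CA,0,
H,CB,0,
H,CG,1,
H,CD2,0,
H,CE1,0,
F,CO,0,
F,CA,0,
F,CB,0,
F,CG,1,
F,CD,0,CD1/CD2
F,CE,0,CE1/CE2
F,CZ,0,
Y,CO,0,
Y,CA,0,
Y,CB,0,
Y,CG,1,
Y,CD,0,CD1/CD2
Y,CE,0,CE1/CE2
Y,CZ,1,
W,CO,0,
W,CA,0,
W,CB,0,
W,CG,1,
W,CD1,0,
W,CD2,1,
W,CE2,1,
W,CE3,0,
W,CZ2,0,
W,CZ3,0,
W,CH2,0,
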