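# Carbon-carbon bonds of the 20 standard amino acids (collapsed convention).
# Atoms bonded only through heteroatoms (Arg CZ, Met CE, His CE1) have no row here
# and are isolated in the carbon bond graph: they yield no one-bond DQ-SQ peak.
# In the collapsed convention the Phe/Tyr ring is the path CG-CD-CE-CZ, which
# preserves all inter-position bond distances of the real six-membered ring.
residue,atom_i,atom_j
G,CO,CA
A,CO,CA
A,CA,CB
S,CO,CA
S,CA,CB
C,CO,CA
C,CA,CB
T,CO,CA
T,CA,CB
T,CB,CG2
V,CO,CA
V,CA,CB
V,CB,CG1
V,CB,CG2
L,CO,CA
L,CA,CB
L,CB,CG
L,CG,CD1
L,CG,CD2
I,CO,CA
I,CA,CB
I,CB,CG1
I,CB,CG2
I,CG1,CD1
P,CO,CA
P,CA,CB
P,CB,CG
P,CG,CD
M,CO,CA
M,CA,CB
M,CB,CG
D,CO,CA
D,CA,CB
D,CB,CG
N,CO,CA
N,CA,CB
N,CB,CG
E,CO,CA
E,CA,CB
E,CB,CG
E,CG,CD
Q,CO,CA
Q,CA,CB
Q,CB,CG
Q,CG,CD
K,CO,CA
K,CA,CB
K,CB,CG
K,CG,CD
K,CD,CE
R,CO,CA
R,CA,CB
R,CB,CG
R,CG,CD
H,CO,CA
H,CA,CB
H,CB,CG
H,CG,CD2
F,CO,CA
F,CA,CB
F,CB,CG
F,CG,CD
F,CD,CE
F,CE,CZ
Y,CO,CA
Y,CA,CB
Y,CB,CG
Y,CG,CD
Y,CD,CE
Y,CE,CZ
W,CO,CA
W,CA,CB
W,CB,CG
W,CG,CD1
W,CG,CD2
W,CD2,CE2
W,CD2,CE3
W,CE2,CZ2
W,CE3,CZ3
W,CZ2,CH2
W,CZ3,CH2
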