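# Per-class (H = helix, S = sheet, C = coil) 13C reference shifts, ppm.
# CA/CB rows (provenance 'csi'): published random-coil values plus consensus
# average helix/sheet secondary shifts (helix dCA +2.6 / dCB -0.4; sheet
# dCA -1.4 / dCB +2.2); Pro ('csi_pro_stats') uses structure-specific
# statistical means because uniform offsets do not apply to proline.
# CO rows ('amide_split'): two-component amide model, 175 ppm helix vs
# 172.5 ppm sheet/coil. class '*' = class-independent side-chain values
# ('fur_fixture' = observed fur shift; 'typical' = typical protein value).
# Users may substitute an alternative table in the same dialect.
residue,atom,class,shift_ppm,sd_ppm,provenance
A,CA,H,55.1,1.0,csi
A,CB,H,18.7,1.0,csi
A,CA,S,51.1,1.0,csi
A,CB,S,21.3,1.0,csi
A,CA,C,52.5,1.0,csi
A,CB,C,19.1,1.0,csi
A,CO,H,175.0,1.0,amide_split
A,CO,S,172.5,1.0,amide_split
A,CO,C,172.5,1.0,amide_split
C,CA,H,60.8,1.0,csi
C,CB,H,27.6,1.0,csi
C,CA,S,56.8,1.0,csi
C,CB,S,30.2,1.0,csi
C,CA,C,58.2,1.0,csi
C,CB,C,28.0,1.0,csi
C,CO,H,175.0,1.0,amide_split
C,CO,S,172.5,1.0,amide_split
C,CO,C,172.5,1.0,amide_split
D,CA,H,56.8,1.0,csi
D,CB,H,40.7,1.0,csi
D,CA,S,52.8,1.0,csi
D,CB,S,43.3,1.0,csi
D,CA,C,54.2,1.0,csi
D,CB,C,41.1,1.0,csi
D,CO,H,175.0,1.0,amide_split
D,CO,S,172.5,1.0,amide_split
D,CO,C,172.5,1.0,amide_split
E,CA,H,59.2,1.0,csi
E,CB,H,29.5,1.0,csi
E,CA,S,55.2,1.0,csi
E,CB,S,32.1,1.0,csi
E,CA,C,56.6,1.0,csi
E,CB,C,29.9,1.0,csi
E,CO,H,175.0,1.0,amide_split
E,CO,S,172.5,1.0,amide_split
E,CO,C,172.5,1.0,amide_split
F,CA,H,60.3,1.0,csi
F,CB,H,39.2,1.0,csi
F,CA,S,56.3,1.0,csi
F,CB,S,41.8,1.0,csi
F,CA,C,57.7,1.0,csi
F,CB,C,39.6,1.0,csi
F,CO,H,175.0,1.0,amide_split
F,CO,S,172.5,1.0,amide_split
F,CO,C,172.5,1.0,amide_split
G,CA,H,47.7,1.0,csi
G,CA,S,43.7,1.0,csi
G,CA,C,45.1,1.0,csi
G,CO,H,175.0,1.0,amide_split
G,CO,S,172.5,1.0,amide_split
G,CO,C,172.5,1.0,amide_split
H,CA,H,57.6,1.0,csi
H,CB,H,28.6,1.0,csi
H,CA,S,53.6,1.0,csi
H,CB,S,31.2,1.0,csi
H,CA,C,55.0,1.0,csi
H,CB,C,29.0,1.0,csi
H,CO,H,175.0,1.0,amide_split
H,CO,S,172.5,1.0,amide_split
H,CO,C,172.5,1.0,amide_split
I,CA,H,63.7,1.0,csi
I,CB,H,38.4,1.0,csi
I,CA,S,59.7,1.0,csi
I,CB,S,41.0,1.0,csi
I,CA,C,61.1,1.0,csi
I,CB,C,38.8,1.0,csi
I,CO,H,175.0,1.0,amide_split
I,CO,S,172.5,1.0,amide_split
I,CO,C,172.5,1.0,amide_split
K,CA,H,58.8,1.0,csi
K,CB,H,32.7,1.0,csi
K,CA,S,54.8,1.0,csi
K,CB,S,35.3,1.0,csi
K,CA,C,56.2,1.0,csi
K,CB,C,33.1,1.0,csi
K,CO,H,175.0,1.0,amide_split
K,CO,S,172.5,1.0,amide_split
K,CO,C,172.5,1.0,amide_split
L,CA,H,57.7,1.0,csi
L,CB,H,42.0,1.0,csi
L,CA,S,53.7,1.0,csi
L,CB,S,44.6,1.0,csi
L,CA,C,55.1,1.0,csi
L,CB,C,42.4,1.0,csi
L,CO,H,175.0,1.0,amide_split
L,CO,S,172.5,1.0,amide_split
L,CO,C,172.5,1.0,amide_split
M,CA,H,58.0,1.0,csi
M,CB,H,32.5,1.0,csi
M,CA,S,54.0,1.0,csi
M,CB,S,35.1,1.0,csi
M,CA,C,55.4,1.0,csi
M,CB,C,32.9,1.0,csi
M,CO,H,175.0,1.0,amide_split
M,CO,S,172.5,1.0,amide_split
M,CO,C,172.5,1.0,amide_split
N,CA,H,55.7,1.0,csi
N,CB,H,38.5,1.0,csi
N,CA,S,51.7,1.0,csi
N,CB,S,41.1,1.0,csi
N,CA,C,53.1,1.0,csi
N,CB,C,38.9,1.0,csi
N,CO,H,175.0,1.0,amide_split
N,CO,S,172.5,1.0,amide_split
N,CO,C,172.5,1.0,amide_split
P,CA,H,65.5,1.0,csi_pro_stats
P,CB,H,31.5,1.0,csi_pro_stats
P,CA,S,62.6,1.0,csi_pro_stats
P,CB,S,32.3,1.0,csi_pro_stats
P,CA,C,63.3,1.0,csi_pro_stats
P,CB,C,31.7,1.0,csi_pro_stats
P,CO,H,175.0,1.0,amide_split
P,CO,S,172.5,1.0,amide_split
P,CO,C,172.5,1.0,amide_split
Q,CA,H,58.3,1.0,csi
Q,CB,H,29.0,1.0,csi
Q,CA,S,54.3,1.0,csi
Q,CB,S,31.6,1.0,csi
Q,CA,C,55.7,1.0,csi
Q,CB,C,29.4,1.0,csi
Q,CO,H,175.0,1.0,amide_split
Q,CO,S,172.5,1.0,amide_split
Q,CO,C,172.5,1.0,amide_split
R,CA,H,58.6,1.0,csi
R,CB,H,30.5,1.0,csi
R,CA,S,54.6,1.0,csi
R,CB,S,33.1,1.0,csi
R,CA,C,56.0,1.0,csi
R,CB,C,30.9,1.0,csi
R,CO,H,175.0,1.0,amide_split
R,CO,S,172.5,1.0,amide_split
R,CO,C,172.5,1.0,amide_split
S,CA,H,60.9,1.0,csi
S,CB,H,63.4,1.0,csi
S,CA,S,56.9,1.0,csi
S,CB,S,66.0,1.0,csi
S,CA,C,58.3,1.0,csi
S,CB,C,63.8,1.0,csi
S,CO,H,175.0,1.0,amide_split
S,CO,S,172.5,1.0,amide_split
S,CO,C,172.5,1.0,amide_split
T,CA,H,64.4,1.0,csi
T,CB,H,69.4,1.0,csi
T,CA,S,60.4,1.0,csi
T,CB,S,72.0,1.0,csi
T,CA,C,61.8,1.0,csi
T,CB,C,69.8,1.0,csi
T,CO,H,175.0,1.0,amide_split
T,CO,S,172.5,1.0,amide_split
T,CO,C,172.5,1.0,amide_split
V,CA,H,64.8,1.0,csi
V,CB,H,32.5,1.0,csi
V,CA,S,60.8,1.0,csi
V,CB,S,35.1,1.0,csi
V,CA,C,62.2,1.0,csi
V,CB,C,32.9,1.0,csi
V,CO,H,175.0,1.0,amide_split
V,CO,S,172.5,1.0,amide_split
V,CO,C,172.5,1.0,amide_split
W,CA,H,60.1,1.0,csi
W,CB,H,29.2,1.0,csi
W,CA,S,56.1,1.0,csi
W,CB,S,31.8,1.0,csi
W,CA,C,57.5,1.0,csi
W,CB,C,29.6,1.0,csi
W,CO,H,175.0,1.0,amide_split
W,CO,S,172.5,1.0,amide_split
W,CO,C,172.5,1.0,amide_split
Y,CA,H,60.7,1.0,csi
Y,CB,H,38.4,1.0,csi
Y,CA,S,56.7,1.0,csi
Y,CB,S,41.0,1.0,csi
Y,CA,C,58.1,1.0,csi
Y,CB,C,38.8,1.0,csi
Y,CO,H,175.0,1.0,amide_split
Y,CO,S,172.5,1.0,amide_split
Y,CO,C,172.5,1.0,amide_split
D,CG,*,179.0,0.5,typical
E,CD,*,182.0,0.5,typical
E,CG,*,34.0,0.5,typical
F,CD,*,130.0,0.5,fur_fixture
F,CE,*,130.0,0.5,fur_fixture
F,CG,*,140.0,0.5,fur_fixture
F,CZ,*,137.0,0.5,fur_fixture
H,CD2,*,120.0,0.5,typical
H,CE1,*,136.0,0.5,typical
H,CG,*,131.0,0.5,typical
I,CD1,*,12.0,0.5,fur_fixture
I,CG1,*,26.0,0.5,fur_fixture
I,CG2,*,14.0,0.5,fur_fixture
K,CD,*,25.0,0.5,fur_fixture
K,CE,*,40.0,0.5,fur_fixture
K,CG,*,25.0,0.5,fur_fixture
L,CD1,*,24.0,0.5,fur_fixture
L,CD2,*,24.0,0.5,fur_fixture
L,CG,*,24.0,0.5,fur_fixture
M,CE,*,17.0,0.5,typical
M,CG,*,32.0,0.5,typical
N,CG,*,177.0,0.5,typical
P,CD,*,48.0,0.5,fur_fixture
P,CG,*,25.0,0.5,fur_fixture
Q,CD,*,180.0,0.5,typical
Q,CG,*,32.0,0.5,typical
R,CD,*,40.0,0.5,fur_fixture
R,CG,*,25.0,0.5,fur_fixture
R,CZ,*,156.0,0.5,fur_fixture
T,CG2,*,20.0,0.5,fur_fixture
V,CG1,*,19.0,0.5,fur_fixture
V,CG2,*,19.0,0.5,fur_fixture
W,CD1,*,127.0,0.5,typical
W,CD2,*,128.0,0.5,typical
W,CE2,*,138.0,0.5,typical
W,CE3,*,120.0,0.5,typical
W,CG,*,110.0,0.5,typical
W,CH2,*,124.0,0.5,typical
W,CZ2,*,114.0,0.5,typical
W,CZ3,*,121.0,0.5,typical
Y,CD,*,130.0,0.5,fur_fixture
Y,CE,*,116.0,0.5,fur_fixture
Y,CG,*,130.0,0.5,fur_fixture
Y,CZ,*,156.0,0.5,fur_fixture
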