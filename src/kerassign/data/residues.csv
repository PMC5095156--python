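# One-letter codes, names, and dietary essentiality (mouse). Isotope labelling of
# non-essential amino acids via dietary 13C is attenuated by de novo biosynthesis
# from unlabelled carbohydrate, so the synthetic generator defaults their
# labelling efficiency below 1.
residue,name,essential
A,alanine,0
R,arginine,1
N,asparagine,0
D,aspartate,0
C,cysteine,0
E,glutamate,0
Q,glutamine,0
G,glycine,0
H,histidine,1
I,isoleucine,1
L,leucine,1
K,lysine,1
M,methionine,1
F,phenylalanine,1
P,proline,0
S,serine,0
T,threonine,1
W,tryptophan,1
Y,tyrosine,0
V,valine,1
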