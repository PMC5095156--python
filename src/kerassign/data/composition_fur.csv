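# Amino acid composition of murine fur (mole %, mean of 3 hydrolysate
# measurements, sd <= 0.4 % for every amino acid; cysteine/cystine and
# tryptophan excluded by the analysis). Glu/Gln and Asp/Asn are not
# distinguished by hydrolysis and are reported as grouped entries.
residue,mole_percent
E/Q,13.58
G,12.95
S,10.45
P,8.35
L,7.45
R,7.32
D/N,6.33
Y,5.67
T,5.58
V,5.41
A,5.14
K,3.68
F,2.95
I,2.93
H,1.18
M,1.02
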