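# BLOSUM62 amino-acid background frequencies (Henikoff & Henikoff target marginals).
A	0.074000
R	0.052000
N	0.045000
D	0.054000
C	0.025000
Q	0.034000
E	0.054000
G	0.074000
H	0.026000
I	0.068000
L	0.099000
K	0.058000
M	0.025000
F	0.047000
P	0.039000
S	0.057000
T	0.051000
W	0.013000
Y	0.032000
V	0.073000
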