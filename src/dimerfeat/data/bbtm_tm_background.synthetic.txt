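# SYNTHETIC stand-in for a beta-barrel TM-segment background (the published
# bbTM TM-matrix frequencies are not redistributable here): BLOSUM62 background
# tilted toward hydrophobic and aromatic residues, renormalized.
# Supply a real 20-vector via config to override.
A	0.081578
R	0.030531
N	0.029200
D	0.035040
C	0.029558
Q	0.022062
E	0.035040
G	0.065468
H	0.017385
I	0.098199
L	0.133301
K	0.036159
M	0.027837
F	0.081259
P	0.030602
S	0.048451
T	0.043786
W	0.015525
Y	0.036717
V	0.102304
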