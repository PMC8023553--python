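# SYNTHETIC stand-in for a TM alpha-helical segment background (the published
# SLIM matrix frequencies are not redistributable here): BLOSUM62 background
# tilted toward hydrophobic residues by exp(0.18 * Kyte-Doolittle), renormalized.
# Supply a real 20-vector via config to override.
A	0.088667
R	0.020047
N	0.020770
D	0.024924
C	0.033978
Q	0.015693
E	0.024924
G	0.059674
H	0.012666
I	0.132467
L	0.170025
K	0.024910
M	0.030499
F	0.067422
P	0.025340
S	0.042772
T	0.038965
W	0.009581
Y	0.021946
V	0.134732
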