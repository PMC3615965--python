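# SwissProt-like amino-acid background frequencies (fraction).
# Source: UniProtKB/Swiss-Prot release composition statistics.
residue	frequency
A	0.082393
C	0.013782
D	0.054429
E	0.067113
F	0.038550
G	0.070608
H	0.022671
I	0.059023
K	0.057925
L	0.098472
M	0.024069
N	0.040547
P	0.047338
Q	0.039249
R	0.055228
S	0.066414
T	0.053530
V	0.068511
W	0.010986
Y	0.029162
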