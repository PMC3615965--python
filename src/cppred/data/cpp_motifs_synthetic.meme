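MEME version 4

ALPHABET= ACDEFGHIKLMNPQRSTVWY

Background letter frequencies
A 0.0824 C 0.0138 D 0.0544 E 0.0671 F 0.0385 G 0.0706 H 0.0227 I 0.0590 K 0.0579 L 0.0985 M 0.0241 N 0.0405 P 0.0473 Q 0.0392 R 0.0552 S 0.0664 T 0.0535 V 0.0685 W 0.0110 Y 0.0292

MOTIF polyR
letter-probability matrix: alength= 20 w= 7 nsites= 40 E= 1.2e-12
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.810000 0.010000 0.010000 0.010000 0.010000 0.010000
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.810000 0.010000 0.010000 0.010000 0.010000 0.010000
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.810000 0.010000 0.010000 0.010000 0.010000 0.010000
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.810000 0.010000 0.010000 0.010000 0.010000 0.010000
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.810000 0.010000 0.010000 0.010000 0.010000 0.010000
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.810000 0.010000 0.010000 0.010000 0.010000 0.010000
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.810000 0.010000 0.010000 0.010000 0.010000 0.010000

MOTIF RxR
letter-probability matrix: alength= 20 w= 5 nsites= 25 E= 3.4e-6
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.810000 0.010000 0.010000 0.010000 0.010000 0.010000
0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.810000 0.010000 0.010000 0.010000 0.010000 0.010000
0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.810000 0.010000 0.010000 0.010000 0.010000 0.010000

MOTIF LKrepeat
letter-probability matrix: alength= 20 w= 8 nsites= 18 E= 8.9e-5
0.200000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.620000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.620000 0.010000 0.010000 0.010000 0.010000 0.010000 0.200000 0.010000 0.010000 0.010000 0.010000 0.010000
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.620000 0.010000 0.010000 0.010000 0.010000 0.010000 0.200000 0.010000 0.010000 0.010000 0.010000 0.010000
0.200000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.620000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000
0.200000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.620000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.620000 0.010000 0.010000 0.010000 0.010000 0.010000 0.200000 0.010000 0.010000 0.010000 0.010000 0.010000
0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.620000 0.010000 0.010000 0.010000 0.010000 0.010000 0.200000 0.010000 0.010000 0.010000 0.010000 0.010000
0.200000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.620000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000 0.010000

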