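# Per-residue physicochemical scales.
# hydrophobicity: Kyte-Doolittle hydropathy (AAindex KYTJ820101)
# amphipathicity: amphiphilicity index (AAindex MITS020101)
# side_chain_bulk: bulkiness (AAindex ZIMJ680102)
# steric_bulk: Charton steric parameter (AAindex CHAM810101)
# h_bond_donors: number of hydrogen-bond donors (AAindex FAUJ880109-style)
# charge: unit charge at physiological pH (R=K=+1, D=E=-1, H=0)
# polar: 1 if side chain is polar (S T C Y N Q D E K R H), else 0
# residue_mass: average residue mass, Da (monoisotopic water excluded;
#   peptide MW = sum of residue masses + one water, 18.01524 Da)
residue	hydrophobicity	amphipathicity	side_chain_bulk	steric_bulk	h_bond_donors	charge	polar	residue_mass
A	1.8	0.0	11.5	0.52	0	0	0	71.0788
C	2.5	0.0	13.46	0.62	1	0	1	103.1388
D	-3.5	0.0	11.68	0.76	1	-1	1	115.0886
E	-3.5	0.0	13.57	0.68	1	-1	1	129.1155
F	2.8	0.58	19.8	0.7	0	0	0	147.1766
G	-0.4	0.0	3.4	0.0	0	0	0	57.0519
H	-3.2	1.34	13.69	0.7	1	0	1	137.1411
I	4.5	0.0	21.4	1.02	0	0	0	113.1594
K	-3.9	3.67	15.71	0.68	2	1	1	128.1741
L	3.8	0.0	21.4	0.98	0	0	0	113.1594
M	1.9	0.0	16.25	0.78	0	0	0	131.1926
N	-3.5	0.0	12.82	0.76	2	0	1	114.1038
P	-1.6	0.0	17.43	0.36	0	0	0	97.1167
Q	-3.5	0.0	14.45	0.68	2	0	1	128.1307
R	-4.5	2.45	14.28	0.68	4	1	1	156.1875
S	-0.8	0.0	9.47	0.53	1	0	1	87.0782
T	-0.7	0.0	15.77	0.5	1	0	1	101.1051
V	4.2	0.0	21.57	0.76	0	0	0	99.1326
W	-0.9	6.93	21.67	0.7	1	0	0	186.2132
Y	-1.3	5.06	18.03	0.7	1	0	1	163.176
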