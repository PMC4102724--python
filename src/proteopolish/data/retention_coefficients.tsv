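# First-order additive retention coefficients (arbitrary hydrophobicity units)
# for peptide RP-HPLC at acidic pH, after the residue coefficients of
# Krokhin et al. (2004) Mol Cell Proteomics 3:908-919 (SSRCalc, 100 A C18).
# Only the first-order additive part of that predictor is used here.
residue	coefficient
W	11.0
F	10.5
L	9.6
I	8.4
M	5.8
V	5.0
Y	4.0
A	0.8
T	0.4
P	0.2
E	0.0
D	-0.5
C	-0.8
S	-0.8
Q	-0.9
G	-0.9
N	-1.2
R	-1.3
H	-1.3
K	-1.9
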