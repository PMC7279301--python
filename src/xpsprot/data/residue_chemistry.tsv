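# Per-residue chemistry for the 20 standard amino acids as in-chain residues
# (free amino acid minus one water). Element columns: C H N O S.
# Environment columns: carbon-environment counts; their sum equals C.
# Assignment policy: backbone Calpha -> C-N; backbone carbonyl -> N-C=O;
# pure-hydrocarbon side chains -> CHx; Ser/Thr Cbeta and Tyr C-OH ring carbon
# -> C-OH; Cys Cbeta, Met Cgamma/Cepsilon -> C-S; Lys Cepsilon, Pro Cdelta,
# Arg Cdelta -> C-N; Arg Czeta (guanidinium) and His Cepsilon1 -> C=N;
# His Cgamma/Cdelta2 and Trp ring carbons bonded to ring N -> C=C-N;
# Phe/Tyr/Trp aromatic carbons with only C/H neighbours -> C=C;
# Asp Cbeta / Glu Cgamma (alpha to carboxyl) -> C-C(O)O; Asp Cgamma /
# Glu Cdelta -> COOH; Asn/Gln side-chain amide carbon -> N-C=O.
residue	C	H	N	O	S	C=C	CHx	C=C-N	C-C(O)O	C-OH	C-N	C=N	N-C=O	C-S	COOH
G	2	3	1	1	0	0	0	0	0	0	1	0	1	0	0
A	3	5	1	1	0	0	1	0	0	0	1	0	1	0	0
V	5	9	1	1	0	0	3	0	0	0	1	0	1	0	0
L	6	11	1	1	0	0	4	0	0	0	1	0	1	0	0
I	6	11	1	1	0	0	4	0	0	0	1	0	1	0	0
P	5	7	1	1	0	0	2	0	0	0	2	0	1	0	0
F	9	9	1	1	0	6	1	0	0	0	1	0	1	0	0
W	11	10	2	1	0	6	1	2	0	0	1	0	1	0	0
M	5	9	1	1	1	0	1	0	0	0	1	0	1	2	0
C	3	5	1	1	1	0	0	0	0	0	1	0	1	1	0
S	3	5	1	2	0	0	0	0	0	1	1	0	1	0	0
T	4	7	1	2	0	0	1	0	0	1	1	0	1	0	0
Y	9	9	1	2	0	5	1	0	0	1	1	0	1	0	0
N	4	6	2	2	0	0	1	0	0	0	1	0	2	0	0
Q	5	8	2	2	0	0	2	0	0	0	1	0	2	0	0
D	4	5	1	3	0	0	0	0	1	0	1	0	1	0	1
E	5	7	1	3	0	0	1	0	1	0	1	0	1	0	1
K	6	12	2	1	0	0	3	0	0	0	2	0	1	0	0
R	6	12	4	1	0	0	2	0	0	0	2	1	1	0	0
H	6	7	3	1	0	0	1	2	0	0	1	1	1	0	0
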