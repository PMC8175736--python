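# Four-state Dayhoff recoding: the six classical Dayhoff exchangeability groups
# collapsed to four, with the aromatic and aliphatic groups merged and cysteine
# treated as ambiguous (X), as in phylogenomic practice for deep bacterial trees.
# columns: residue	code
A	A
G	A
P	A
S	A
T	A
D	T
E	T
N	T
Q	T
H	G
K	G
R	G
F	C
I	C
L	C
M	C
V	C
W	C
Y	C
C	X
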