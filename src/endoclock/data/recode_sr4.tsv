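# Four-state amino-acid recoding after Susko & Roger (2007), groups chosen to
# minimise compositional heterogeneity; residues mapped onto nucleotide symbols.
# columns: residue	code
A	A
G	A
N	A
P	A
S	A
T	A
C	C
H	C
W	C
Y	C
D	G
E	G
K	G
Q	G
R	G
F	T
I	T
L	T
M	T
V	T
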