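# Murphy 10-class reduced amino-acid alphabet (Murphy, Wallqvist & Levy 2000).
# residue <TAB> class representative
A	A
C	C
D	E
E	E
F	F
G	G
H	H
I	L
K	K
L	L
M	L
N	E
P	P
Q	E
R	K
S	S
T	S
V	L
W	F
Y	F
X	X
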