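aa	value
P	1.00
E	0.78
S	0.71
Q	0.66
K	0.59
A	0.45
G	0.44
D	0.41
T	0.40
R	0.39
M	0.29
N	0.28
V	0.26
H	0.26
L	0.20
F	0.12
Y	0.11
I	0.09
W	0.00
C	0.00
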