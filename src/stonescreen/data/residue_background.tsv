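# Background amino-acid frequencies for the synthetic proteome generator.
# Approximate vertebrate/Swiss-Prot average composition; normalized at load.
residue	frequency
A	0.0825
R	0.0553
N	0.0406
D	0.0545
C	0.0137
Q	0.0393
E	0.0675
G	0.0707
H	0.0227
I	0.0596
L	0.0966
K	0.0584
M	0.0242
F	0.0386
P	0.0470
S	0.0656
T	0.0534
W	0.0108
Y	0.0292
V	0.0687
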