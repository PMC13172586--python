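# Four-state secondary-structure propensities used by the built-in
# window-averaged predictor.
# helix / strand / turn columns are the Chou-Fasman conformational
# parameters (P_alpha, P_beta, P_turn). The coil column is a package-defined
# stand-in: coil(res) = turn(res) - 0.05, except for the canonical
# coil-formers glycine and proline, which get turn(res) + 0.20.
# The predictor is a documented stand-in for alignment-database methods such
# as SOPMA and is not expected to reproduce their per-protein output.
residue	helix	strand	turn	coil
A	1.42	0.83	0.66	0.61
R	0.98	0.93	0.95	0.90
N	0.67	0.89	1.56	1.51
D	1.01	0.54	1.46	1.41
C	0.70	1.19	1.19	1.14
Q	1.11	1.10	0.98	0.93
E	1.51	0.37	0.74	0.69
G	0.57	0.75	1.56	1.76
H	1.00	0.87	0.95	0.90
I	1.08	1.60	0.47	0.42
L	1.21	1.30	0.59	0.54
K	1.16	0.74	1.01	0.96
M	1.45	1.05	0.60	0.55
F	1.13	1.38	0.60	0.55
P	0.57	0.55	1.52	1.72
S	0.77	0.75	1.43	1.38
T	0.83	1.19	0.96	0.91
W	1.08	1.37	0.96	0.91
Y	0.69	1.47	1.14	1.09
V	1.06	1.70	0.50	0.45
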