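# RNA/RNA nearest-neighbor Gibbs free energies at 37 C, 1 M NaCl, kcal/mol
# source: Xia et al. 1998 Watson-Crick parameters (Turner rules)
# version: 1.0
# Stack steps are keyed by the 5'->3' dinucleotide on the reference strand;
# the partner strand is its Watson-Crick complement. Strand symmetry makes
# step XY equal step comp(Y)comp(X), so the 10 unique published parameters
# expand to all 16 steps below.
step	dG37
AA	-0.93
AC	-2.24
AG	-2.08
AU	-1.10
CA	-2.11
CC	-3.26
CG	-2.36
CU	-2.08
GA	-2.35
GC	-3.42
GG	-3.26
GU	-2.24
UA	-1.33
UC	-2.35
UG	-2.11
UU	-0.93
INIT	4.09
TERM_AU	0.45
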