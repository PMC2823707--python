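# Nearest-neighbor stack parameters, RNA/RNA (Watson-Crick, Xia et al. 1998).
# One stack per line: <5'->3' dinucleotide of the keyed strand> <dH kcal/mol> <dS cal/(K mol)>.
AA	-6.82	-19.0
AU	-9.38	-26.7
AC	-11.40	-29.5
AG	-10.48	-27.1
UA	-7.69	-20.5
UU	-6.82	-19.0
UC	-12.44	-32.5
UG	-10.44	-26.9
CA	-10.44	-26.9
CU	-10.48	-27.1
CC	-13.39	-32.7
CG	-10.64	-26.7
GA	-12.44	-32.5
GU	-11.40	-29.5
GC	-14.88	-36.9
GG	-13.39	-32.7
init	3.61	-1.5
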