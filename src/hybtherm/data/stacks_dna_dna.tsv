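# Nearest-neighbor stack parameters, DNA/DNA (unified set, SantaLucia 1998).
# One stack per line: <5'->3' dinucleotide of the keyed strand> <dH kcal/mol> <dS cal/(K mol)>.
# The antiparallel complement strand is implied (Watson-Crick).
# 'init' line: duplex initiation dH dS. Set to zero here: helix initiation
# for melting-temperature work is carried by the A term of the Tm equation.
AA	-7.9	-22.2
AT	-7.2	-20.4
AC	-8.4	-22.4
AG	-7.8	-21.0
TA	-7.2	-21.3
TT	-7.9	-22.2
TC	-8.2	-22.2
TG	-8.5	-22.7
CA	-8.5	-22.7
CT	-7.8	-21.0
CC	-8.0	-19.9
CG	-10.6	-27.2
GA	-8.2	-22.2
GT	-8.4	-22.4
GC	-9.8	-24.4
GG	-8.0	-19.9
init	0.0	0.0
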