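# Loop free-energy penalties for DNA secondary structure, dG at 37 C (kcal/mol).
# Grammar: "<loop_kind> <size> <dG37>" for hairpin/bulge/internal anchor sizes,
#          "multiloop <a> <b> <c>" for the linear multiloop model
#          E_ml = a + b * (interior branches) + c * (unpaired bases).
# Sizes between anchors (and beyond the largest anchor) are filled by
# Jacobson-Stockmayer extrapolation dG(n) = dG(anchor) + 1.75 R T ln(n/anchor).
hairpin	3	3.5
hairpin	4	3.5
hairpin	5	3.3
hairpin	6	4.0
hairpin	7	4.2
hairpin	8	4.3
hairpin	9	4.5
hairpin	10	4.6
hairpin	12	5.0
hairpin	14	5.3
hairpin	16	5.6
hairpin	18	5.8
hairpin	20	5.9
hairpin	25	6.3
hairpin	30	6.6
bulge	1	4.0
bulge	2	2.9
bulge	3	3.1
bulge	4	3.2
bulge	5	3.3
bulge	6	3.5
bulge	7	3.7
bulge	8	3.9
bulge	9	4.1
bulge	10	4.3
bulge	12	4.5
bulge	14	4.8
bulge	16	5.0
bulge	18	5.2
bulge	20	5.3
bulge	25	5.6
bulge	30	5.9
internal	2	4.1
internal	3	3.2
internal	4	3.6
internal	5	4.0
internal	6	4.4
internal	7	4.6
internal	8	4.8
internal	9	4.9
internal	10	4.9
internal	12	5.2
internal	14	5.4
internal	16	5.6
internal	18	5.8
internal	20	5.9
internal	25	6.3
internal	30	6.6
multiloop	3.4	0.4	0.0
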